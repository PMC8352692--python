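# Methods

This note documents the models, parameter choices and numerical conventions
behind `cc-extract`, and what the synthetic validation does and does not
show.

## Trilevel thresholding

All four criteria operate on the 256-bin normalized histogram only; they are
invariant under any permutation of pixels.  Three thresholds induce **four**
classes `[0,t1], (t1,t2], (t2,t3], (t3,255]` with `1 ≤ t1 < t2 < t3 ≤ 254`
(each class spans at least one bin; a class may still carry zero mass).
The inclusive-upper convention makes the equal-mass split of a uniform
histogram fall at `T = (63,127,191)` with four 64-bin classes.  Conventions:
natural logarithms, `0·ln 0 ≡ 0`, and an empty class contributes zero
entropy / zero variance, so sparse histograms never produce NaNs.

*Otsu.* Between-class variance over the four classes.  The implementation
satisfies the conservation law (between-class) + (pooled within-class) =
(total variance) for every threshold triple; the test suite checks this to
1e−9 over a thousand random histograms.

*Kapur and Shannon.* Both are sums of the Shannon entropies of the
class-normalized histogram segments.  The thresholding literature sometimes
distinguishes a mass-weighted variant; `shannon_form="weighted"` switches to
`Σ ω_k H_k`, which is a lower bound of the sum form (class masses are ≤ 1).
The default form is the unweighted sum for both criteria.

*Tsallis.* Per-class non-extensive entropy
`S_q = (1 − Σ (p_i/θ)^q)/(q−1)` on class-normalized probabilities, composed
as `Σ_k S_q(k) + (1−q) Π_k S_q(k)` (the pseudo-additive rule applied with a
single product correction).  The entropic index defaults to `q = 0.8` and is
configurable; `q = 1` is rejected with a pointer to the Shannon criterion.
As `q → 1` the objective converges to the Shannon sum form *linearly* in
`|q−1|`, with first-order coefficient `Σ_k M_k/2 + Π_k H_k`
(`M_k = Σ r ln² r` over the class-normalized distribution).  For full-range
histograms that coefficient is of order 10²; the gap is ≈ 3·10⁻² at
`|q−1| = 10⁻⁴` and shrinks proportionally (≈ 3·10⁻⁴ at 10⁻⁶).  Tests assert
the linear convergence; no fixed small tolerance at `|q−1| = 10⁻⁴` can hold
for generic histograms.

A shared prefix-sum engine evaluates all criteria in O(1) per triple after
O(L) preprocessing, and the exhaustive oracle enumerates every valid triple
with the *same* floating-point expressions, so stochastic-search scores are
exactly comparable with the enumerated maximum (ties included).  Enumeration
ties break toward the lexicographically smallest triple.

## Chaotic cuckoo search

A population of 30 nests holds candidate triples as floating-point vectors;
integer evaluation uses a repair step (round → clamp → sort →
separate ties by unit shifts).  Per generation each nest proposes
`X' = X + α·s∘(X_best − X)` (per-coordinate step factors `s`), a greedy rule
replaces a randomly chosen nest when the proposal scores higher, the
incumbent best is updated elitistically (score ties break toward the
lexicographically smaller triple, which lets the search drift across score
plateaus such as the uniform histogram's), and the worst ⌈p_a·30⌉ nests are
abandoned and re-randomized uniformly.  A proposal that rounds back onto its
own nest is nudged by one unit in a random coordinate so a converged
population keeps probing the integer neighborhood of the incumbent.
Defaults: 1500 generations, `α = 1`, `p_a = 0.25`, fixed-length runs
(an optional patience enables early stopping).

**Step driver.**  The printed one-dimensional Ikeda reduction
`IM = R·exp(φ − δ/(1+c²))` with `R = 0.75, φ = 0.1, δ = 7` is exposed as
`ikeda_next` (both groupings of the iteration index `Z` are implemented, and
the output is clamped to `[1e−12, 1e3]` so the `with_Z` reading stays
finite).  This map is *contractive*: every start in (0,1) collapses onto the
fixed point `0.75·e^{−6.9} ≈ 7.565·10⁻⁴` within two iterations, so used as a
step factor it freezes the guided move (a sub-10⁻³ step times any in-range
distance rounds to zero).  The package therefore drives CCS with the
canonical **two-dimensional Ikeda map**
(`t = 0.4 − 6/(1+x²+y²)`, `x' = 1 + u(x cos t − y sin t)`,
`y' = u(x sin t + y cos t)`, dissipation `u = 0.9`), whose chaotic
x-orbit spans roughly [−0.6, 1.8] and yields both interpolating and
overshooting moves relative to the incumbent.  `driver="printed"` and
`step_mode="literal"` retain the degenerate readings for fidelity
experiments.  The Lévy-flight baseline (TCS) draws Mantegna steps with
stability 1.5.

On a benchmark of eighty runs (twenty random 64-level histograms × four
criteria) at the defaults, CCS reaches the enumerated maximum in ≈ 99% of
runs and, sharing the oracle's arithmetic, can never exceed it.  Identical
seeds reproduce runs byte-for-byte.

## Synthetic phantom

Each phantom emulates a mid-sagittal T1 slice on a 256×256 grid:

| element | default | rationale |
| --- | --- | --- |
| brain ellipse | semi-axes (80, 95) px | head-sized region in a 256² frame |
| background level | 20 | dark air/CSF surround |
| tissue shells | 100 (outer), 150 (inner) | gray / white matter means |
| CC crescent | half-annulus, r 30–40 px, level 180 | thin arch, 30 gray levels above white matter — close but distinct |
| skull ring (optional) | level 240, outside a dark gap | bright cranium |
| noise | additive Gaussian, σ = 3 (suite: 2–4), clipped to [0,255] | acquisition noise scale at which tissue modes stay separable |

The generator is bit-reproducible from its seed, validates that the crescent
lies strictly inside the brain, flags (without enforcing) crescents within
2σ of the nearest tissue level, and returns exact crescent and brain masks.
The default cohort cycles contrast gaps of 15–35 gray levels and noise
σ ∈ {2, 3, 4}.  Noiseless phantoms are deliberately *not* part of the
cohort: their histograms are four delta peaks, for which entropy criteria
are degenerate (all mass in one class maximizes class-normalized entropy);
they are constructed explicitly in tests that need an exact level set.

What the phantom does **not** emulate: anatomy (the crescent is a geometric
annulus sector), partial-volume effects, bias fields, Rician noise
statistics, or the intensity overlap of real T1 tissue distributions.
Passing phantom tests therefore demonstrates the pipeline's mechanics —
threshold placement between separable modes, contour convergence to crisp
edges, exact flood recovery of an isolated class — not clinical-grade
accuracy on real MRI.

## Active contour

The edge indicator is `g = 1/(1 + β|∇I_σ|²)` on the min–max [0,1]-rescaled
image with central-difference gradients and Gaussian pre-smoothing σ = 1 px.
Because gradients of a normalized image are small (a 20–30 gray-level step
smoothed by one pixel has `|∇I| ≈ 0.03–0.08`), the edge-sensitivity constant
must be large: the default `β = 2000` maps the weakest relevant edge to
`g ≲ 0.3` while mildly noisy flat regions stay near 1.  The contour evolves
by the morphological level-set scheme (scikit-image's
`morphological_geodesic_active_contour`) with one curvature-smoothing pass
per iteration, balloon weight +1 (inflation from small operator seeds) that
is disabled where `g < 0.4`, up to 500 iterations with a convergence check
every 25 (stop when under 0.1% of pixels change).  Inputs are despeckled
with a 3×3 median filter first: on quantized noisy slices a few percent of
tissue pixels fall in the wrong intensity class, and those isolated flips
otherwise bridge the region boundary and let the balloon leak (measured on
the cohort: mean Dice 0.75 without the filter, 0.97 with it).  The final
mask is the connected component containing the seed; a collapsed contour
returns an empty mask with a logged warning.

The scikit-image morphological snakes alternate their curvature operator
through module-level state; `gac_extract` resets that cycle on entry so
identical inputs give identical outputs regardless of process history.

Known limitation: the discrete curvature regularization rounds sharp
corners, so even initialized at the exact boundary the equilibrium Dice on
a *thin* (10 px) crescent is ≈ 0.98; on thicker structures it exceeds 0.99.

## Region growing and skull stripping

Region growing is a deterministic breadth-first flood accepting a neighbor
when its intensity is within `tol` of the running region mean (reference
`"seed"` switches to the fixed seed value; 4- or 8-connectivity).  With
`tol = 0` on a quantized noiseless phantom the crescent class is recovered
exactly (Dice 1.0).  The running-mean rule is monotone in `tol` on
piecewise-constant inputs; on noisy images monotonicity is not guaranteed
in general.

Skull stripping is intentionally minimal: Otsu bi-level binarization,
morphological opening (disk radius 2), selection of the largest connected
component, then hole filling.  Holes are filled only *after* component
selection — filling first would flood the dark gap enclosed by the skull
ring and fuse ring and brain.  This suffices for phantoms and clean slices;
it is not a substitute for dedicated brain-extraction tools on real MRI.

## Evaluation conventions

False-negative and false-positive rates are the exact complements
`1 − sensitivity` and `1 − specificity` (computed as such, so the complement
identities hold to the last bit); the union-normalized set-difference
variants are available via `legacy_setrates=True`.  Empty-vs-empty masks
score Jaccard = Dice = 1; zero-denominator rates report 0 and are flagged.
Batch evaluation appends an unweighted arithmetic mean row.  TBA/CCA are
reported as raw pixel counts, image-normalized fractions, and the CCA/TBA
ratio; no single normalization is canonical for comparing against published
area tables, so all three are given.

## Problem sizes used in validation

The optimizer benchmark uses twenty 64-level histograms per criterion
(enumeration over all ~36k triples is exact and fast); conservation and
limit checks use 1000 and 100 random 256-bin histograms; the end-to-end
cohort is ten phantoms.  These sizes make the full validation run in about
a minute on one CPU while keeping every check statistically meaningful.
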