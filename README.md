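# cc-extract

Extraction and evaluation of the **corpus callosum (CC)** from 2D sagittal
brain-MRI slices.

The corpus callosum — the arched white-matter commissure joining the two
hemispheres — is clinically important (its size is studied in autism-spectrum
research), but it is hard to segment: in T1-weighted MRI its intensity is
close to that of the surrounding white matter.  `cc-extract` implements a
two-stage, operator-seeded pipeline for 256×256 sagittal slices:

1. **Preprocessing — trilevel thresholding.**  Three thresholds
   `T = (t1, t2, t3)` partition the gray-level histogram into four classes
   `[0,t1], (t1,t2], (t2,t3], (t3,255]`, and the slice is quantized to the
   class means.  Four criteria over the normalized histogram
   `p_0..p_255` are available:
   - *Otsu*: between-class variance `F(T) = Σ_k ω_k (μ_k − μ_T)²`;
   - *Kapur*: sum of class-normalized Shannon entropies
     `F(T) = Σ_k H_k`, `H_k = −Σ_{i∈Q_k} (p_i/θ_k) ln(p_i/θ_k)`;
   - *Shannon*: same sum form by default (a mass-weighted variant
     `Σ_k ω_k H_k` is selectable);
   - *Tsallis* (index `q`): `Σ_k S_q(k) + (1−q) Π_k S_q(k)` with
     `S_q = (1 − Σ (p_i/θ)^q)/(q−1)`, recovering Shannon as `q → 1`.

   The maximizing triple is found by **chaotic cuckoo search (CCS)** — a
   cuckoo-search population (30 nests, 1500 generations, step scale α=1,
   abandonment fraction p_a=0.25) whose step factors come from the orbit of
   the Ikeda map — with a Lévy-flight traditional cuckoo search (TCS)
   baseline and an exhaustive-enumeration oracle for validation.

2. **Postprocessing — seeded extraction.**  From an operator-placed seed in
   the quantized slice, either a **geodesic active contour** (edge indicator
   `g = 1/(1 + β|∇I|²)`, curvature + edge-attraction + balloon evolution,
   morphological level-set discretization) or **region growing**
   (breadth-first flood within an intensity tolerance of the region's
   running mean) extracts the CC.  A minimal morphological skull stripper
   removes the cranial ring when present.

Extractions are scored against ground truth with Jaccard, Dice
(`D = 2J/(1+J)`), FPR/FNR, sensitivity, specificity, accuracy and precision,
plus total-brain-area (TBA) and CC-area (CCA) measures.

Because public MRI cohorts cannot ship with the package, a deterministic
**synthetic phantom** generator renders 256×256 brain-slice look-alikes
(elliptical brain with nested tissue shells, a thin CC-like crescent of
nearby intensity, optional skull ring, Gaussian noise) together with exact
ground-truth masks, so the whole pipeline is testable end to end.

## Worked example

Render a phantom, then run the full pipeline (Shannon criterion + CCS, then
active-contour extraction) against its ground truth:

```sh
cc-extract phantom --n 1 --seed 3 --outdir fixtures/
cc-extract pipeline --in slice.png --objective shannon --method gac \
    --seed-rc 83,128 --seed 1 --gt gt.png --out-mask cc.png
```

```json
{
  "extracted_pixels": 1136,
  "metrics": {
    "accuracy": 0.9992828369140625,
    "dice": 0.9791574279379157,
    "jaccard": 0.9591659426585578,
    "sensitivity": 0.9865951742627346,
    "specificity": 0.9995032367232253
  },
  "objective": "shannon",
  "score": 8.745629017456938,
  "thresholds": [23, 102, 153]
}
```

The optimizer placed the thresholds in the three histogram gaps
(background | gray matter | white matter | CC), the quantized slice isolated
the crescent as its brightest class, and the active contour recovered it
with Dice ≈ 0.98 against the exact phantom mask.  Library use mirrors the
CLI: `optimize_thresholds`, `apply_thresholds`, `gac_extract` /
`region_grow`, `metrics_report`.

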