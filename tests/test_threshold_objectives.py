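"""Thresholding criteria: analytic values, conservation laws, and agreement
with naive from-the-definition implementations and brute-force enumeration."""

import itertools

import numpy as np
import pytest

from cc_extract import (
    Histogram,
    ObjectiveKind,
    apply_thresholds,
    compute_histogram,
    exhaustive_best,
    kapur_objective,
    make_objective,
    otsu_objective,
    shannon_objective,
    total_variance,
    tsallis_objective,
    validate_thresholds,
    within_class_variance,
)

# --- naive reference implementations, written directly from the definitions;
# --- they share no code with the package's prefix-sum engine.


def _ranges(T, L):
    t1, t2, t3 = T
    return [(0, t1), (t1 + 1, t2), (t2 + 1, t3), (t3 + 1, L - 1)]


def naive_otsu(p, T):
    L = len(p)
    mu_T = sum(i * p[i] for i in range(L))
    out = 0.0
    for lo, hi in _ranges(T, L):
        w = sum(p[lo : hi + 1])
        if w > 0:
            mu = sum(i * p[i] for i in range(lo, hi + 1)) / w
            out += w * (mu - mu_T) ** 2
    return out


def naive_entropy_sum(p, T, weighted=False):
    L = len(p)
    out = 0.0
    for lo, hi in _ranges(T, L):
        w = sum(p[lo : hi + 1])
        if w > 0:
            h = -sum(
                (p[i] / w) * np.log(p[i] / w) for i in range(lo, hi + 1) if p[i] > 0
            )
            out += w * h if weighted else h
    return out


def naive_tsallis(p, T, q):
    L = len(p)
    terms = []
    for lo, hi in _ranges(T, L):
        w = sum(p[lo : hi + 1])
        if w > 0:
            s = (1.0 - sum((p[i] / w) ** q for i in range(lo, hi + 1) if p[i] > 0)) / (
                q - 1.0
            )
        else:
            s = 0.0
        terms.append(s)
    return sum(terms) + (1.0 - q) * np.prod(terms)


def _random_hist(rng, nbins=64, sparse=False):
    counts = rng.integers(0 if sparse else 1, 500, size=nbins)
    return Histogram(counts)


def _random_T(rng, nbins):
    return tuple(sorted(rng.choice(np.arange(1, nbins - 1), size=3, replace=False)))


# --- histogram basics


def test_histogram_counts_and_probs():
    img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
    h = compute_histogram(img)
    assert h.total == 4
    assert h.probs[0] == 0.5 and h.probs[255] == 0.5
    const = np.full((5, 5), 7, dtype=np.uint8)
    hc = compute_histogram(const)
    assert hc.probs[7] == 1.0 and hc.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_threshold_validation_rejects_bad_triples():
    for bad in [(0, 10, 20), (10, 10, 20), (20, 10, 30), (1, 2, 255)]:
        with pytest.raises(ValueError):
            validate_thresholds(bad, 256)


# --- analytic objective values


def test_otsu_two_delta_value():
    """Half the mass at 50 and half at 200: any separating triple scores
    0.5*75^2 + 0.5*75^2 = 5625 exactly."""
    counts = np.zeros(256, dtype=int)
    counts[50] = counts[200] = 1000
    h = Histogram(counts)
    for T in [(50, 100, 150), (60, 199, 220), (50, 51, 254)]:
        assert otsu_objective(h, T) == pytest.approx(5625.0, abs=1e-9)


def test_otsu_single_bin_is_zero():
    counts = np.zeros(256, dtype=int)
    counts[100] = 123
    h = Histogram(counts)
    for T in [(1, 2, 3), (99, 150, 200), (100, 101, 102)]:
        assert otsu_objective(h, T) == pytest.approx(0.0, abs=1e-12)


def test_kapur_uniform_equal_split():
    """Uniform histogram, T=(63,127,191): four classes of 64 equiprobable bins,
    each contributing ln 64."""
    h = Histogram(np.ones(256, dtype=int))
    assert kapur_objective(h, (63, 127, 191)) == pytest.approx(4 * np.log(64), abs=1e-9)
    assert shannon_objective(h, (63, 127, 191)) == pytest.approx(
        4 * np.log(64), abs=1e-9
    )


def test_entropy_of_degenerate_distribution_is_zero():
    counts = np.zeros(256, dtype=int)
    counts[42] = 9
    h = Histogram(counts)
    assert kapur_objective(h, (10, 100, 200)) == 0.0
    assert shannon_objective(h, (50, 100, 200)) == 0.0
    assert tsallis_objective(h, (50, 100, 200), q=0.8) == 0.0


def test_tsallis_two_state_entropy():
    """Two equiprobable states in one class, q=2: S_q = (1-0.5)/(2-1) = 0.5."""
    counts = np.zeros(256, dtype=int)
    counts[10] = counts[20] = 5
    h = Histogram(counts)
    # T placing both deltas into the first class and leaving the rest empty
    assert tsallis_objective(h, (30, 100, 200), q=2.0) == pytest.approx(0.5, abs=1e-12)


def test_tsallis_rejects_q_one():
    h = Histogram(np.ones(256, dtype=int))
    with pytest.raises(ValueError):
        tsallis_objective(h, (63, 127, 191), q=1.0)


def test_tsallis_limit_scales_linearly_to_shannon(rng):
    """The Tsallis criterion approaches the Shannon criterion linearly in
    |q-1| (the limit claim); the gap at |q-1|=1e-6 is ~100x the gap at 1e-4."""
    h = _random_hist(rng, 256)
    T = (63, 127, 191)
    s = shannon_objective(h, T)
    d4 = abs(tsallis_objective(h, T, 1 + 1e-4) - s)
    d6 = abs(tsallis_objective(h, T, 1 + 1e-6) - s)
    assert d6 < d4 / 50
    assert d6 < 1e-3


def test_shannon_weighted_never_exceeds_sum_form(rng):
    """Class masses are <= 1, so the mass-weighted form is a lower bound."""
    for _ in range(50):
        h = _random_hist(rng, 64, sparse=True)
        T = _random_T(rng, 64)
        assert shannon_objective(h, T, form="weighted") <= shannon_objective(h, T) + 1e-12


@pytest.mark.parametrize("name,q", [("otsu", None), ("kapur", None),
                                    ("shannon", None), ("tsallis", 0.8),
                                    ("tsallis", 2.0)])
def test_objectives_match_naive_definitions(rng, name, q):
    """The prefix-sum engine agrees with direct from-the-definition loops on
    random sparse histograms (including empty classes and zero bins)."""
    for _ in range(20):
        h = _random_hist(rng, 64, sparse=True)
        T = _random_T(rng, 64)
        p = h.probs
        if name == "otsu":
            got, want = otsu_objective(h, T), naive_otsu(p, T)
        elif name == "kapur":
            got, want = kapur_objective(h, T), naive_entropy_sum(p, T)
        elif name == "shannon":
            got, want = (
                shannon_objective(h, T, "weighted"),
                naive_entropy_sum(p, T, weighted=True),
            )
        else:
            got, want = tsallis_objective(h, T, q), naive_tsallis(p, T, q)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


def test_objectives_depend_only_on_histogram(rng):
    """Permuting pixels leaves every criterion unchanged."""
    img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    shuffled = rng.permutation(img.ravel()).reshape(img.shape)
    T = (63, 127, 191)
    h1, h2 = compute_histogram(img), compute_histogram(shuffled)
    assert np.array_equal(h1.counts, h2.counts)
    assert otsu_objective(h1, T) == otsu_objective(h2, T)
    assert kapur_objective(h1, T) == kapur_objective(h2, T)


def test_otsu_variance_conservation(rng):
    """Between-class + pooled within-class variance equals the total
    histogram variance for every threshold triple."""
    for _ in range(200):
        h = _random_hist(rng, 64, sparse=True)
        if h.total == 0:
            continue
        T = _random_T(rng, 64)
        total = total_variance(h)
        assert otsu_objective(h, T) + within_class_variance(h, T) == pytest.approx(
            total, abs=1e-9
        )


# --- quantization


def test_apply_thresholds_constant_image():
    img = np.full((8, 8), 77, dtype=np.uint8)
    assert np.array_equal(apply_thresholds(img, (10, 100, 200)), img)


def test_apply_thresholds_two_delta_image():
    img = np.where(np.arange(64).reshape(8, 8) < 32, 50, 200).astype(np.uint8)
    out = apply_thresholds(img, (100, 150, 220))
    assert set(np.unique(out)) == {50, 200}


def test_apply_thresholds_at_most_four_levels(rng):
    img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
    out = apply_thresholds(img, (40, 120, 210))
    assert len(np.unique(out)) <= 4


# --- exhaustive oracle


def _brute_force(h, kind):
    """Plain triple loop over every valid T using the naive evaluators."""
    p = h.probs
    L = h.nbins
    best, bestT = -np.inf, None
    for T in itertools.combinations(range(1, L - 1), 3):
        if kind.name == "otsu":
            v = naive_otsu(p, T)
        elif kind.name in ("kapur", "shannon"):
            v = naive_entropy_sum(p, T)
        else:
            v = naive_tsallis(p, T, kind.q)
        if v > best + 1e-12:
            best, bestT = v, T
    return bestT, best


@pytest.mark.parametrize("name", ["otsu", "kapur", "tsallis"])
def test_exhaustive_best_matches_brute_force(rng, name):
    kind = ObjectiveKind(name)
    h = _random_hist(rng, 16)
    T, score = exhaustive_best(h, kind)
    bT, bscore = _brute_force(h, kind)
    assert score == pytest.approx(bscore, rel=1e-10)
    assert T == bT


def test_exhaustive_best_two_delta_lexicographic_tie_break():
    """All separating triples score 5625; the lexicographically smallest wins."""
    counts = np.zeros(64, dtype=int)
    counts[10] = counts[50] = 7
    h = Histogram(counts)
    T, score = exhaustive_best(h, ObjectiveKind("otsu"))
    assert score == pytest.approx(naive_otsu(h.probs, T), rel=1e-12)
    # smallest separating triple in lexicographic order: (1, 2, 10) puts the
    # first delta in class [3, 10] and the second in [11, 63]
    assert T == (1, 2, 10)


def test_exhaustive_best_uniform_kapur_equal_split():
    h = Histogram(np.ones(256, dtype=int))
    T, score = exhaustive_best(h, ObjectiveKind("kapur"))
    assert T == (63, 127, 191)
    assert score == pytest.approx(4 * np.log(64), abs=1e-9)


def test_exhaustive_best_dominates_random_probes(rng):
    h = _random_hist(rng, 64)
    kind = ObjectiveKind("kapur")
    _, best = exhaustive_best(h, kind)
    f = make_objective(h, kind)
    for _ in range(500):
        assert f(_random_T(rng, 64)) <= best
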