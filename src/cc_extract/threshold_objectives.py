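"""Trilevel thresholding objectives over an image histogram.

Three thresholds ``T = (t1, t2, t3)`` partition the gray-level range into four
classes ``[0, t1], (t1, t2], (t2, t3], (t3, L-1]``.  Four criteria score a
candidate ``T`` from the normalized histogram alone:

* **Otsu** — between-class variance ``sum_k w_k (mu_k - mu_T)^2``;
* **Kapur** — sum of the Shannon entropies of the class-normalized segments;
* **Shannon** — by default identical in form to Kapur's criterion (sum of
  class-normalized entropies); a mass-weighted variant ``sum_k w_k H_k`` is
  selectable via ``shannon_form="weighted"``;
* **Tsallis** — non-extensive entropy with index ``q``, composed over the four
  classes with the pseudo-additive correction ``(1-q) * prod_k S_q(k)``.

All four depend on the image only through its histogram, use natural
logarithms, and adopt ``0 * ln 0 == 0``; an empty class (zero probability
mass) contributes zero entropy / zero variance.  ``exhaustive_best`` is a
brute-force enumeration of every valid threshold triple, used as the oracle
against which the stochastic optimizer is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Histogram",
    "ObjectiveKind",
    "compute_histogram",
    "validate_thresholds",
    "class_slices",
    "otsu_objective",
    "kapur_objective",
    "shannon_objective",
    "tsallis_objective",
    "total_variance",
    "within_class_variance",
    "make_objective",
    "apply_thresholds",
    "exhaustive_best",
]

DEFAULT_LEVELS = 256
#: Default Tsallis entropic index (the non-extensivity parameter q).
DEFAULT_Q = 0.8


@dataclass(frozen=True)
class Histogram:
    """Gray-level histogram: integer counts plus the normalized distribution."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 4:
            raise ValueError("histogram needs a 1-D array of at least 4 bins")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def nbins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(self.nbins, dtype=float)
        return self.counts / float(total)

    @classmethod
    def from_probs(cls, probs: np.ndarray, scale: int = 10**9) -> "Histogram":
        """Build an (approximate) integer-count histogram from a distribution."""
        probs = np.asarray(probs, dtype=float)
        return cls(np.rint(probs * scale).astype(np.int64))


def compute_histogram(img: np.ndarray, levels: int = DEFAULT_LEVELS) -> Histogram:
    """Histogram of an 8-bit grayscale image (counts sum to the pixel count)."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot histogram an empty image")
    if img.min() < 0 or img.max() >= levels:
        raise ValueError(f"pixel values must lie in [0, {levels - 1}]")
    counts = np.bincount(img.ravel().astype(np.int64), minlength=levels)
    return Histogram(counts)


@dataclass(frozen=True)
class ObjectiveKind:
    """Which criterion to optimize; carries the Tsallis index and Shannon form."""

    name: str
    q: float = DEFAULT_Q
    shannon_form: str = "sum"

    def __post_init__(self) -> None:
        if self.name not in ("otsu", "kapur", "shannon", "tsallis"):
            raise ValueError(f"unknown objective {self.name!r}")
        if self.name == "tsallis":
            if not (self.q > 0) or self.q == 1.0:
                raise ValueError("tsallis requires q > 0 and q != 1")
        if self.shannon_form not in ("sum", "weighted"):
            raise ValueError("shannon_form must be 'sum' or 'weighted'")


def validate_thresholds(T, nbins: int = DEFAULT_LEVELS) -> tuple[int, int, int]:
    """Check 1 <= t1 < t2 < t3 <= L-2 and return the triple as plain ints."""
    t = tuple(int(v) for v in T)
    if len(t) != 3:
        raise ValueError("a threshold vector has exactly three components")
    t1, t2, t3 = t
    if not (1 <= t1 < t2 < t3 <= nbins - 2):
        raise ValueError(
            f"thresholds must satisfy 1 <= t1 < t2 < t3 <= {nbins - 2}, got {t}"
        )
    return t1, t2, t3


def class_slices(T, nbins: int = DEFAULT_LEVELS) -> list[tuple[int, int]]:
    """Inclusive (lo, hi) bin ranges of the four classes induced by ``T``."""
    t1, t2, t3 = validate_thresholds(T, nbins)
    return [(0, t1), (t1 + 1, t2), (t2 + 1, t3), (t3 + 1, nbins - 1)]


# ---------------------------------------------------------------------------
# Internal engine: prefix sums shared by the scalar evaluators and the
# exhaustive enumeration, so that both paths produce bit-identical scores.
# ---------------------------------------------------------------------------


def _cum0(x: np.ndarray) -> np.ndarray:
    out = np.zeros(x.size + 1, dtype=float)
    np.cumsum(x, out=out[1:])
    return out


@dataclass
class _Prefix:
    nbins: int
    p: np.ndarray  # cumulative probability mass
    pi: np.ndarray  # cumulative sum of p_i * i
    pii: np.ndarray  # cumulative sum of p_i * i^2
    plogp: np.ndarray  # cumulative sum of p_i * ln p_i  (0 where p_i == 0)
    pq: dict = field(default_factory=dict)  # q -> cumulative sum of p_i^q

    @classmethod
    def build(cls, h: Histogram) -> "_Prefix":
        p = h.probs
        i = np.arange(h.nbins, dtype=float)
        safe = np.where(p > 0, p, 1.0)
        plogp = np.where(p > 0, p * np.log(safe), 0.0)
        return cls(h.nbins, _cum0(p), _cum0(p * i), _cum0(p * i * i), _cum0(plogp))

    def power_cum(self, q: float) -> np.ndarray:
        if q not in self.pq:
            p = np.diff(self.p)
            self.pq[q] = _cum0(np.where(p > 0, p, 0.0) ** q)
        return self.pq[q]


def _bounds(t1, t2, t3, nbins):
    """Per-class (lo, hi+1) cumulative-array indices for the four classes."""
    los = (np.zeros_like(t1), t1 + 1, t2 + 1, t3 + 1)
    his = (t1 + 1, t2 + 1, t3 + 1, np.full_like(t1, nbins))
    return los, his


def _otsu_scores(pref: _Prefix, t1, t2, t3):
    los, his = _bounds(t1, t2, t3, pref.nbins)
    mu_total = pref.pi[-1]
    score = 0.0
    for lo, hi in zip(los, his):
        w = pref.p[hi] - pref.p[lo]
        m = pref.pi[hi] - pref.pi[lo]
        mu = np.where(w > 0, m / np.where(w > 0, w, 1.0), 0.0)
        score = score + np.where(w > 0, w * (mu - mu_total) ** 2, 0.0)
    return score


def _entropy_scores(pref: _Prefix, t1, t2, t3, weighted: bool):
    los, his = _bounds(t1, t2, t3, pref.nbins)
    score = 0.0
    for lo, hi in zip(los, his):
        w = pref.p[hi] - pref.p[lo]
        a = pref.plogp[hi] - pref.plogp[lo]
        ws = np.where(w > 0, w, 1.0)
        hk = np.where(w > 0, np.log(ws) - a / ws, 0.0)
        score = score + (w * hk if weighted else hk)
    return score


def _tsallis_scores(pref: _Prefix, t1, t2, t3, q: float):
    cq = pref.power_cum(q)
    los, his = _bounds(t1, t2, t3, pref.nbins)
    terms = []
    for lo, hi in zip(los, his):
        w = pref.p[hi] - pref.p[lo]
        s = cq[hi] - cq[lo]
        ws = np.where(w > 0, w, 1.0)
        terms.append(np.where(w > 0, (1.0 - s / ws**q) / (q - 1.0), 0.0))
    s0, s1, s2, s3 = terms
    return (s0 + s1 + s2 + s3) + (1.0 - q) * (s0 * s1 * s2 * s3)


def _score_fn(pref: _Prefix, kind: ObjectiveKind):
    if kind.name == "otsu":
        return lambda t1, t2, t3: _otsu_scores(pref, t1, t2, t3)
    if kind.name == "kapur":
        return lambda t1, t2, t3: _entropy_scores(pref, t1, t2, t3, weighted=False)
    if kind.name == "shannon":
        weighted = kind.shannon_form == "weighted"
        return lambda t1, t2, t3: _entropy_scores(pref, t1, t2, t3, weighted=weighted)
    return lambda t1, t2, t3: _tsallis_scores(pref, t1, t2, t3, kind.q)


# ---------------------------------------------------------------------------
# Public objective functions
# ---------------------------------------------------------------------------


def otsu_objective(h: Histogram, T) -> float:
    """Between-class variance of the four classes induced by ``T``."""
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    return float(_otsu_scores(_Prefix.build(h), t1, t2, t3))


def kapur_objective(h: Histogram, T) -> float:
    """Sum of the Shannon entropies of the class-normalized histogram segments."""
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    return float(_entropy_scores(_Prefix.build(h), t1, t2, t3, weighted=False))


def shannon_objective(h: Histogram, T, form: str = "sum") -> float:
    """Shannon criterion; ``form='weighted'`` gives ``sum_k w_k H_k`` instead."""
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    kind = ObjectiveKind("shannon", shannon_form=form)
    weighted = kind.shannon_form == "weighted"
    return float(_entropy_scores(_Prefix.build(h), t1, t2, t3, weighted=weighted))


def tsallis_objective(h: Histogram, T, q: float = DEFAULT_Q) -> float:
    """Tsallis criterion with pseudo-additive composition over the four classes.

    The per-class term is ``S_q = (1 - sum (p_i/P_k)^q) / (q - 1)`` on the
    class-normalized probabilities, and the total is
    ``sum_k S_q(k) + (1 - q) * prod_k S_q(k)``.  Recovers the Shannon
    criterion (sum form) in the limit ``q -> 1``.
    """
    if q == 1.0:
        raise ValueError("q=1 is the Shannon limit; use shannon_objective instead")
    if not q > 0:
        raise ValueError("the entropic index q must be positive")
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    return float(_tsallis_scores(_Prefix.build(h), t1, t2, t3, q))


def total_variance(h: Histogram) -> float:
    """Variance of the gray-level distribution."""
    p = h.probs
    i = np.arange(h.nbins, dtype=float)
    mu = float(np.sum(p * i))
    return float(np.sum(p * (i - mu) ** 2))


def within_class_variance(h: Histogram, T) -> float:
    """Pooled within-class variance ``sum_k w_k sigma_k^2`` for the classes of ``T``."""
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    pref = _Prefix.build(h)
    los, his = _bounds(np.int64(t1), np.int64(t2), np.int64(t3), h.nbins)
    out = 0.0
    for lo, hi in zip(los, his):
        w = pref.p[hi] - pref.p[lo]
        if w > 0:
            m1 = (pref.pi[hi] - pref.pi[lo]) / w
            m2 = (pref.pii[hi] - pref.pii[lo]) / w
            out += w * (m2 - m1 * m1)
    return float(out)


def make_objective(h: Histogram, kind: ObjectiveKind):
    """Fast scalar evaluator ``f(T) -> score`` bound to one histogram.

    Shares its prefix-sum arithmetic with :func:`exhaustive_best` so optimizer
    scores are directly comparable with the enumeration oracle.
    """
    pref = _Prefix.build(h)
    fn = _score_fn(pref, kind)

    def objective(T) -> float:
        t1, t2, t3 = (int(T[0]), int(T[1]), int(T[2]))
        return float(fn(np.int64(t1), np.int64(t2), np.int64(t3)))

    return objective


def apply_thresholds(img: np.ndarray, T) -> np.ndarray:
    """Quantize an image: replace each pixel by its class's mean gray level."""
    img = np.asarray(img)
    h = compute_histogram(img)
    t1, t2, t3 = validate_thresholds(T, h.nbins)
    counts = h.counts.astype(float)
    i = np.arange(h.nbins, dtype=float)
    levels = np.empty(4, dtype=np.uint8)
    for k, (lo, hi) in enumerate(class_slices(T, h.nbins)):
        c = counts[lo : hi + 1].sum()
        if c > 0:
            mean = (counts[lo : hi + 1] * i[lo : hi + 1]).sum() / c
        else:  # class empty in the image: fall back to the range midpoint
            mean = 0.5 * (lo + hi)
        levels[k] = np.uint8(np.clip(np.rint(mean), 0, h.nbins - 1))
    cls = np.searchsorted(np.array([t1, t2, t3]), img, side="left")
    return levels[cls]


def exhaustive_best(h: Histogram, kind: ObjectiveKind) -> tuple[tuple[int, int, int], float]:
    """Enumerate every valid (t1, t2, t3) and return the maximizer.

    Ties are broken by the lexicographically smallest triple.  This is the
    ground-truth oracle for the threshold search: no valid triple scores
    higher under the same floating-point evaluation.
    """
    if h.total == 0:
        raise ValueError("cannot optimize an empty histogram")
    L = h.nbins
    pref = _Prefix.build(h)
    fn = _score_fn(pref, kind)
    best_score = -np.inf
    best_T = None
    t2g, t3g = np.meshgrid(
        np.arange(2, L - 2, dtype=np.int64),
        np.arange(3, L - 1, dtype=np.int64),
        indexing="ij",
    )
    for t1 in range(1, L - 3):
        sel = (t2g > t1) & (t3g > t2g)
        t2v = t2g[sel]
        t3v = t3g[sel]
        scores = fn(np.full_like(t2v, t1), t2v, t3v)
        k = int(np.argmax(scores))  # first occurrence == lexicographically smallest
        if scores[k] > best_score:
            best_score = float(scores[k])
            best_T = (int(t1), int(t2v[k]), int(t3v[k]))
    return best_T, best_score
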