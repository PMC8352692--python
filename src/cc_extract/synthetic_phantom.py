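"""Deterministic 256x256 brain-slice phantoms with exact ground truth.

Each phantom emulates a mid-sagittal T1 slice: an elliptical "brain" made of
two or three nested tissue shells (gray matter outside, white matter inside),
a thin crescent — an annulus sector — standing in for the corpus callosum
whose intensity sits close to, but distinct from, the surrounding white
matter, an optional bright "skull" ring separated from the brain by a dark
gap, and additive Gaussian noise clipped to [0, 255].  Exact binary masks of
the crescent and of the brain ellipse are returned alongside the image, so
every downstream stage (thresholding, segmentation, evaluation) can be scored
against a known truth without any external MRI data.

Phantoms are bit-reproducible: the same spec and seed always give the same
image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CrescentSpec",
    "PhantomSpec",
    "crescent_mask",
    "crescent_area",
    "generate_phantom",
    "cc_seed_point",
    "true_thresholds",
    "phantom_suite",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrescentSpec:
    """Annulus-sector geometry of the synthetic corpus callosum.

    ``orient_deg`` is the direction (degrees, 0 = +column axis, 90 = up) of
    the sector's bisector; ``span_deg`` is its total angular extent.
    """

    center: tuple[float, float] = (118.0, 128.0)  # (row, col)
    r_outer: float = 40.0
    r_inner: float = 30.0
    span_deg: float = 180.0
    orient_deg: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("need 0 < r_inner < r_outer")
        if not 0 < self.span_deg <= 360:
            raise ValueError("span_deg must lie in (0, 360]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom (defaults are the study conditions).

    Intensities are mean gray levels: ``background_level`` outside the head,
    ``tissue_levels`` for the nested brain shells (outermost first, e.g. gray
    matter then white matter), ``cc_level`` for the crescent and
    ``skull_level`` for the optional ring.  ``noise_sigma`` is the standard
    deviation (gray levels) of the additive Gaussian noise.
    """

    seed: int = 0
    size: int = 256
    brain_center: tuple[float, float] = (128.0, 128.0)
    brain_axes: tuple[float, float] = (80.0, 95.0)  # (row, col) semi-axes
    background_level: int = 20
    tissue_levels: tuple[int, ...] = (100, 150)
    cc_level: int = 180
    cc_geometry: CrescentSpec = field(default_factory=CrescentSpec)
    skull: bool = False
    skull_level: int = 240
    noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        levels = (self.background_level, *self.tissue_levels, self.cc_level)
        if any(not 0 <= v <= 255 for v in levels):
            raise ValueError("all mean gray levels must lie in [0, 255]")
        if len(self.tissue_levels) < 1:
            raise ValueError("at least one intra-brain tissue level is required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def low_contrast(self) -> bool:
        """True when the crescent is within 2*sigma of its nearest tissue level."""
        gap = min(abs(self.cc_level - t) for t in self.tissue_levels)
        return gap < 2.0 * self.noise_sigma


def _ellipse_mask(size: int, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def crescent_mask(size: int, spec: CrescentSpec) -> np.ndarray:
    """Rasterize the annulus sector (pixel centers inside the region)."""
    rr, cc = np.ogrid[:size, :size]
    dy = spec.center[0] - rr  # image rows grow downward; flip to y-up
    dx = cc - spec.center[1]
    r2 = dx * dx + dy * dy
    radial = (r2 >= spec.r_inner**2) & (r2 <= spec.r_outer**2)
    ang = np.degrees(np.arctan2(dy, dx))
    delta = np.abs((ang - spec.orient_deg + 180.0) % 360.0 - 180.0)
    return radial & (delta <= spec.span_deg / 2.0)


def crescent_area(spec: CrescentSpec) -> float:
    """Analytic area of the annulus sector in pixels."""
    return (
        math.pi
        * (spec.r_outer**2 - spec.r_inner**2)
        * (spec.span_deg / 360.0)
    )


def cc_seed_point(spec: PhantomSpec) -> tuple[int, int]:
    """A pixel guaranteed to lie inside the crescent (mid-radius, mid-angle)."""
    g = spec.cc_geometry
    r = 0.5 * (g.r_inner + g.r_outer)
    a = math.radians(g.orient_deg)
    row = int(round(g.center[0] - r * math.sin(a)))
    col = int(round(g.center[1] + r * math.cos(a)))
    return row, col


def true_thresholds(spec: PhantomSpec) -> tuple[int, int, int]:
    """Threshold triple at the midpoints of the gaps between the four largest
    mean levels (background, tissues, crescent), isolating the crescent class
    on a noiseless phantom.

    Only defined for phantoms with exactly two intra-brain tissue levels (four
    structural levels in total, matching the trilevel setting).
    """
    levels = sorted((spec.background_level, *spec.tissue_levels, spec.cc_level))
    if len(levels) != 4:
        raise ValueError("true_thresholds requires exactly four structural levels")
    return tuple((levels[k] + levels[k + 1]) // 2 for k in range(3))


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(image, cc_gt, brain_gt)`` where ``image`` is a uint8
    ``size x size`` slice and the masks are boolean arrays marking exactly the
    crescent and the brain ellipse.  Raises ``ValueError`` if the crescent is
    not strictly inside the brain ellipse.
    """
    size = spec.size
    brain = _ellipse_mask(size, spec.brain_center, spec.brain_axes)
    cc = crescent_mask(size, spec.cc_geometry)
    if np.any(cc & ~brain):
        raise ValueError("the crescent must lie strictly inside the brain ellipse")
    if spec.low_contrast:
        logger.warning(
            "low-contrast phantom: |cc_level - nearest tissue| < 2*noise_sigma"
        )

    img = np.full((size, size), float(spec.background_level))
    n = len(spec.tissue_levels)
    for k, level in enumerate(spec.tissue_levels):
        scale = 1.0 - 0.38 * k / max(n - 1, 1) if n > 1 else 1.0
        shell = _ellipse_mask(
            size,
            spec.brain_center,
            (spec.brain_axes[0] * scale, spec.brain_axes[1] * scale),
        )
        img[shell] = float(level)
    img[cc] = float(spec.cc_level)
    if spec.skull:
        outer = _ellipse_mask(
            size, spec.brain_center, (spec.brain_axes[0] * 1.18, spec.brain_axes[1] * 1.18)
        )
        inner = _ellipse_mask(
            size, spec.brain_center, (spec.brain_axes[0] * 1.10, spec.brain_axes[1] * 1.10)
        )
        img[outer & ~inner] = float(spec.skull_level)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, cc, brain


_SUITE_CC_LEVELS = (180, 175, 170, 185)
_SUITE_SIGMAS = (2.0, 3.0, 4.0)


def phantom_suite(n: int, base_seed: int):
    """A reproducible cohort of ``n`` phantoms with varied contrast and noise.

    Contrast (crescent vs. white matter) cycles over gaps of 15-35 gray levels
    and the noise standard deviation cycles over {2, 3, 4} gray levels —
    realistic acquisition noise; noiseless phantoms are degenerate (their
    histograms are sums of delta peaks) and are constructed explicitly where a
    noise-free fixture is wanted.  Each phantom's RNG is seeded from
    ``(base_seed, index)`` so the suite is order-independent.

    Returns a list of ``(image, cc_gt, brain_gt, spec)`` tuples.
    """
    out = []
    for i in range(n):
        spec = PhantomSpec(
            seed=(base_seed * 1_000_003 + i) % (2**31),
            cc_level=_SUITE_CC_LEVELS[i % len(_SUITE_CC_LEVELS)],
            noise_sigma=_SUITE_SIGMAS[i % len(_SUITE_SIGMAS)],
        )
        img, cc, brain = generate_phantom(spec)
        out.append((img, cc, brain, spec))
    return out


def vary(spec: PhantomSpec, **changes) -> PhantomSpec:
    """Convenience wrapper over dataclasses.replace for building variants."""
    return replace(spec, **changes)
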