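"""Reading, writing and geometric normalization of 2D slices and masks.

Working geometry: 8-bit grayscale slices of 256 x 256 pixels.  2D rasters
(PNG/TIFF) are loaded as single-channel uint8 (RGB collapses to luminance
with a warning; wider dtypes are min-max rescaled).  NIfTI volumes are sliced
along the sagittal axis and the extracted plane min-max rescaled to [0, 255].
Binary masks travel as {0, 255} PNGs; any nonzero pixel is foreground on
read.  Coordinates are 0-based (row, column).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage import transform
from skimage.measure import block_reduce

__all__ = [
    "load_slice",
    "normalize_geometry",
    "save_image",
    "save_mask",
    "load_mask",
]

logger = logging.getLogger(__name__)

TARGET_SIZE = 256
_RGB_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])
_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _rescale_u8(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale any numeric array to uint8 [0, 255]."""
    arr = np.asarray(arr, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_slice(path, slice_index: int | None = None, axis: int = 0) -> np.ndarray:
    """Load a 2D 8-bit grayscale slice from a raster file or a NIfTI volume.

    For volumes, ``slice_index`` selects the plane along ``axis`` (the first
    voxel axis by default, the usual sagittal axis of RAS-oriented T1
    volumes; ``None`` takes the middle plane) and the plane is min-max
    rescaled to [0, 255].  8-bit 2D rasters pass through unchanged; RGB input
    collapses to luminance with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    if _is_nifti(path):
        try:
            vol = np.asanyarray(nib.load(str(path)).dataobj)
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
        if vol.ndim == 2:
            return _rescale_u8(vol)
        if vol.ndim != 3:
            raise ValueError(f"{path}: expected a 2D or 3D volume, got {vol.ndim}D")
        n = vol.shape[axis]
        if slice_index is None:
            slice_index = n // 2
            logger.info("no slice_index given; using the middle plane %d", slice_index)
        if not 0 <= slice_index < n:
            raise IndexError(
                f"slice_index {slice_index} out of bounds for axis {axis} (size {n})"
            )
        plane = np.take(vol, slice_index, axis=axis)
        return _rescale_u8(plane)

    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("%s: RGB input converted to grayscale by luminance", path)
        arr = arr[..., :3].astype(float) @ _RGB_WEIGHTS
        arr = np.rint(arr).astype(np.uint8) if arr.max() <= 255 else arr
    if arr.dtype == np.uint8:
        return arr
    return _rescale_u8(arr)


def normalize_geometry(img: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Resample a grayscale slice to ``size x size`` 8-bit.

    Downscaling averages over areas (exact block means for integer shrink
    factors), upscaling is bilinear; both preserve the mean intensity to
    within a gray level.  Idempotent on already-conforming images.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("normalize_geometry expects a 2D grayscale image")
    if img.shape == (size, size):
        return img.astype(np.uint8, copy=True)
    h, w = img.shape
    f = img.astype(float)
    if h % size == 0 and w % size == 0:
        out = block_reduce(f, (h // size, w // size), np.mean)
    else:
        out = transform.resize(
            f,
            (size, size),
            order=1,
            anti_aliasing=(h > size or w > size),
            preserve_range=True,
            mode="reflect",
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def save_image(img: np.ndarray, path) -> None:
    """Write an 8-bit grayscale image as PNG/TIFF."""
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit {0, 255} raster."""
    m = np.asarray(mask)
    iio.imwrite(Path(path), np.where(m.astype(bool), 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a mask raster; any nonzero value is foreground.

    Values other than {0, 255} are coerced to foreground with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read mask: no such file {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        logger.warning("%s: non-binary raster; values > 0 coerced to foreground", path)
    return arr > 0
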