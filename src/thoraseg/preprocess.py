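"""HU normalization and in-plane resizing.

CT attenuation is windowed with fixed clinical bounds (−1000 HU, air, to
400 HU, dense soft tissue) and min-max scaled into [0, 1]; values outside the
window are clipped.  Slices are resized in-plane to a small square grid
(default 128×128) with bilinear interpolation for images and nearest
neighbour for masks; the z axis is never resampled.  The effective in-plane
pixel spacing after resizing is the source spacing scaled by
``source_dim / target_dim`` and is what mm-based surface metrics should use.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .errors import DimensionError

__all__ = [
    "HU_LO",
    "HU_HI",
    "TARGET_SIZE",
    "normalize_hu",
    "resize_slice",
    "rescaled_spacing",
    "preprocess_volume",
]

HU_LO = -1000.0
HU_HI = 400.0
TARGET_SIZE = (128, 128)


def normalize_hu(values: np.ndarray, lo: float = HU_LO, hi: float = HU_HI) -> np.ndarray:
    """Clip HU to ``[lo, hi]`` and min-max scale into [0, 1].

    Monotone non-decreasing; ``lo`` maps to 0.0 and ``hi`` to 1.0 exactly.
    """
    if lo >= hi:
        raise ValueError(f"lower HU bound must be below upper bound, got {lo} >= {hi}")
    values = np.asarray(values, dtype=np.float64)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def resize_slice(
    image: np.ndarray,
    target: tuple[int, int] = TARGET_SIZE,
    mode: str = "bilinear",
) -> np.ndarray:
    """Resize one 2D slice to ``target``; bilinear for images, nearest for masks."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise DimensionError(f"resize_slice expects a 2D array, got ndim={image.ndim}")
    if min(image.shape) < 2:
        raise DimensionError(f"degenerate slice shape {image.shape}")
    if tuple(image.shape) == tuple(target):
        return image.copy()
    if mode == "bilinear":
        return resize(image.astype(np.float64), target, order=1, anti_aliasing=False, preserve_range=True)
    if mode == "nearest":
        out = resize(image, target, order=0, anti_aliasing=False, preserve_range=True)
        return out.astype(image.dtype)
    raise ValueError(f"unknown resize mode {mode!r}")


def rescaled_spacing(
    source_shape: tuple[int, int],
    source_spacing: tuple[float, float],
    target: tuple[int, int] = TARGET_SIZE,
) -> tuple[float, float]:
    """In-plane (y, x) spacing of the resized grid in mm."""
    return (
        source_spacing[0] * source_shape[0] / target[0],
        source_spacing[1] * source_shape[1] / target[1],
    )


def preprocess_volume(
    voxels: np.ndarray,
    lo: float = HU_LO,
    hi: float = HU_HI,
    target: tuple[int, int] = TARGET_SIZE,
    is_mask: bool = False,
) -> np.ndarray:
    """Normalize (images only) and resize every slice of a (z, y, x) volume."""
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise DimensionError(f"expected a 3D volume, got ndim={voxels.ndim}")
    if is_mask:
        slices = [resize_slice(s, target, mode="nearest") for s in voxels]
        return np.stack(slices).astype(np.uint8)
    norm = normalize_hu(voxels, lo=lo, hi=hi)
    return np.stack([resize_slice(s, target, mode="bilinear") for s in norm])
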