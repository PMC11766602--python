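"""Raster preprocessing: grayscale conversion, binarization, skeletonization.

The registration core consumes skeletonized binary vessel maps. Retinal
vessels vary in width, so segmentation masks are thinned to unit-width
centerlines before matching; this removes vessel-caliber variation that
would otherwise dominate the correlation score.

Conventions: images are 2-D float arrays with intensities in [0, 1]
(``GrayImage``); masks are 2-D uint8 arrays with values {0, 1}
(``BinaryMask``). Row-major, origin top-left, x = column, y = row, 0-based.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import ParameterError, UnsupportedFormatError

__all__ = [
    "to_grayscale",
    "binarize",
    "skeletonize",
    "load_image",
    "load_mask",
    "save_mask",
    "save_image",
]

#: ITU-R 601 luminance weights for RGB -> gray reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce a 1- or 3-channel raster to a single channel in [0, 1].

    3-channel input is reduced with fixed luminance weights
    (0.299, 0.587, 0.114); 1-channel input is passed through. Integer inputs
    are rescaled by their dtype's full range; float inputs must already lie
    in [0, 1].
    """
    arr = np.asarray(image)
    if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
        raise UnsupportedFormatError("image contains non-finite values")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 1:
        gray = arr[:, :, 0]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ LUMA_WEIGHTS
    else:
        raise UnsupportedFormatError(
            f"expected 1 or 3 channels, got array of shape {arr.shape}"
        )
    if gray.size == 0:
        raise UnsupportedFormatError("empty image")
    if gray.min() < 0 or gray.max() > 1 + 1e-9:
        raise UnsupportedFormatError("float image values must lie in [0, 1]")
    return np.clip(gray, 0.0, 1.0)


def binarize(map_: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability/intensity map to a {0, 1} mask.

    A pixel maps to foreground iff its value is >= ``threshold`` (ties go to
    foreground). The default 0.5 is the conventional cut on a probabilistic
    vessel map.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    arr = np.asarray(map_, dtype=float)
    return (arr >= threshold).astype(np.uint8)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to unit-width centerlines (morphological thinning).

    Uses 8-connected Zhang–Suen-style thinning; the output foreground is a
    subset of the input foreground, connected components are preserved, and
    the operation is idempotent.
    """
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, [0, 1])):
        raise ParameterError("mask must be binary with values {0, 1}")
    return _skimage_skeletonize(arr.astype(bool), method="zhang").astype(np.uint8)


# -- raster I/O ------------------------------------------------------------


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster and return a GrayImage in [0, 1]."""
    return to_grayscale(iio.imread(path))


def load_mask(path: str | Path, threshold: float = 0.5) -> np.ndarray:
    """Read a raster and binarize it (8-bit {0, 255} masks round-trip exactly)."""
    return binarize(load_image(path), threshold)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a BinaryMask as an 8-bit raster with values {0, 255}."""
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a GrayImage (or HxWx3 float RGB) in [0, 1] as an 8-bit raster."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))
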