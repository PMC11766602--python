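"""Training data sources: synthetic fundus-like pairs and DRIVE-style folders."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import ParameterError
from ..preprocessing import load_image, load_mask
from ..synthetic import VesselTreeParams, generate_vessel_tree

__all__ = ["synthetic_training_pairs", "load_drive_folder"]


def render_fundus(mask: np.ndarray, seed: int = 0) -> np.ndarray:
    """Render a vessel mask as a fundus-photograph-like grayscale image.

    Vessels appear dark on a brighter, smoothly varying background with mild
    sensor noise — the photometric situation a vessel segmenter faces.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = 0.65 + 0.1 * np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / h)
    vessels = gaussian_filter(mask.astype(float), 0.6)
    img = bg - 0.4 * np.clip(vessels, 0, 1) + rng.normal(0, 0.02, size=mask.shape)
    return np.clip(img, 0.0, 1.0)


def synthetic_training_pairs(
    n: int, size: int = 64, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` (image, mask) pairs of synthetic vasculature at ``size``²."""
    pairs = []
    for i in range(n):
        mask = generate_vessel_tree(VesselTreeParams(seed=seed + i, size=size))
        pairs.append((render_fundus(mask, seed=seed + i), mask))
    return pairs


def load_drive_folder(root: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read DRIVE-layout training data: ``images/`` plus ``1st_manual/`` masks.

    Files are paired by sorted order; images come back as grayscale [0, 1]
    arrays and masks as {0, 1}. Raises if the folders are missing or the
    counts differ.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "1st_manual"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise ParameterError(f"{root} lacks images/ and 1st_manual/ subfolders")
    images = sorted(p for p in img_dir.iterdir() if not p.name.startswith("."))
    masks = sorted(p for p in mask_dir.iterdir() if not p.name.startswith("."))
    if len(images) != len(masks) or not images:
        raise ParameterError(
            f"found {len(images)} images but {len(masks)} masks under {root}"
        )
    return [(load_image(i), load_mask(m)) for i, m in zip(images, masks)]
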