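"""Paired geometric + photometric training augmentation.

A single random geometric transform (rotation, flips, shear about the image
center) is applied identically to the image and its mask — bilinear for the
image, nearest-neighbor for the mask so it stays binary — and photometric
jitter (brightness offset, contrast gain) is applied to the image only.
Deterministic under an integer seed.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform
from skimage.transform import warp as _warp

from ..errors import ParameterError

__all__ = ["augment_pair"]


def _geometric_transform(rng: np.random.Generator, cfg, shape) -> AffineTransform:
    h, w = shape
    rot = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    flip_x = -1.0 if cfg.flip_lr and rng.random() < 0.5 else 1.0
    flip_y = -1.0 if cfg.flip_ud and rng.random() < 0.5 else 1.0
    center = AffineTransform(translation=(-(w - 1) / 2, -(h - 1) / 2))
    core = AffineTransform(rotation=rot, shear=shear, scale=(flip_x, flip_y))
    back = AffineTransform(translation=((w - 1) / 2, (h - 1) / 2))
    return AffineTransform(matrix=back.params @ core.params @ center.params)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly augment an (image, mask) pair with a shared geometry.

    ``config`` is an :class:`~ipcc_ar.segmentation.unet.AugmentConfig`;
    ranges of zero (and flips disabled) return the pair unchanged.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ParameterError("image and mask sizes differ")
    rng = np.random.default_rng(seed)
    no_geometry = (
        config.rotation_deg == 0
        and config.shear_deg == 0
        and not config.flip_lr
        and not config.flip_ud
    )
    if not no_geometry:
        tform = _geometric_transform(rng, config, mask.shape[:2])
        inv = tform.inverse
        image = _warp(image, inv, order=1, cval=0.0, preserve_range=True)
        mask = _warp(mask.astype(float), inv, order=0, cval=0.0, preserve_range=True)
        mask = (mask >= 0.5).astype(np.uint8)
    if config.brightness > 0:
        image = image + rng.uniform(-config.brightness, config.brightness)
    if config.contrast > 0:
        gain = 1.0 + rng.uniform(-config.contrast, config.contrast)
        image = (image - 0.5) * gain + 0.5
    return np.clip(image, 0.0, 1.0), mask
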