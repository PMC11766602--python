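"""Synthetic retinal-vasculature fixtures with known ground-truth motion.

Real inputs to the registration pipeline are vessel-segmentation maps of the
retina: trees of curvilinear branches radiating from the optic disc, thick
near the disc and tapering distally. The generator emulates exactly that
geometry — seeded random-walk branches stamped as discs, branching with a
per-step probability and a per-level width decay — because patch-wise
correlation only sees local curvilinear structure, not photometric detail.

A fixture pair is a generated "pre-operative" map plus a "intra-operative"
counterpart produced by a *known* similarity transform (rotation, uniform
scale, translation about the image center), optionally degraded by a
rectangular instrument-shaped occlusion band and an illumination change
(grayscale variant). The known transform is the ground truth against which
registration accuracy is measured.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import GenerationError, ParameterError
from .ipcc import warp
from .transform import SimilarityTransform

__all__ = [
    "VesselTreeParams",
    "FixturePair",
    "generate_vessel_tree",
    "make_fixture_pair",
    "random_fixture",
    "add_occlusion",
    "reprojection_error",
]

#: Acceptable vessel-pixel fraction of a generated mask (before thinning).
DENSITY_BAND = (0.02, 0.20)


@dataclass(frozen=True)
class VesselTreeParams:
    """Knobs of the vessel-tree random walk.

    Defaults produce 256x256 masks whose foreground fraction falls inside
    ``DENSITY_BAND``, comparable to fundus vessel maps: a handful of arcades
    leaving the optic-disc margin, branching a few times, tapering with each
    generation.
    """

    seed: int = 0
    size: int = 256
    n_roots: int = 5
    branch_prob: float = 0.01  # per step
    max_depth: int = 4  # branching generations
    initial_width: float = 5.0  # px
    width_decay: float = 0.8  # per generation
    tortuosity: float = 0.15  # rad of heading jitter per step

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ParameterError("size must be >= 64")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ParameterError("branch_prob must be in [0, 1]")
        if self.initial_width < 1:
            raise ParameterError("initial_width must be >= 1 px")


@dataclass(frozen=True)
class FixturePair:
    """A fixed/moving mask pair related by a known similarity transform."""

    fixed: np.ndarray
    moving: np.ndarray
    truth: SimilarityTransform
    occlusion_fraction: float = 0.0
    moving_gray: np.ndarray | None = None


def _render_discs(
    size: int, xs: list[float], ys: list[float], radii: list[float]
) -> np.ndarray:
    """Union of discs, rendered by radius bucket with morphological dilation."""
    img = np.zeros((size, size), dtype=bool)
    if not xs:
        return img.astype(np.uint8)
    x = np.round(xs).astype(int)
    y = np.round(ys).astype(int)
    r = np.maximum(np.round(np.asarray(radii) * 2) / 2, 0.5)  # half-px buckets
    inside = (x >= 0) & (x < size) & (y >= 0) & (y < size)
    x, y, r = x[inside], y[inside], r[inside]
    for rq in np.unique(r):
        canvas = np.zeros((size, size), dtype=bool)
        canvas[y[r == rq], x[r == rq]] = True
        k = int(np.ceil(rq))
        yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
        struct = xx * xx + yy * yy <= rq * rq
        img |= ndimage.binary_dilation(canvas, structure=struct)
    return img.astype(np.uint8)


def _grow_tree(params: VesselTreeParams, max_depth: int, attempt: int) -> np.ndarray:
    rng = np.random.default_rng([params.seed, attempt])
    size = params.size
    xs: list[float] = []
    ys: list[float] = []
    radii: list[float] = []
    # Optic-disc margin: roots fan out radially from a circle left of center,
    # as vessel arcades do on a fundus photograph.
    disc = np.array([0.38 * size, 0.50 * size])
    disc_r = 0.08 * size
    step = 1.2
    # (x, y, heading, width, depth)
    queue: list[tuple[float, float, float, float, int]] = []
    for k in range(params.n_roots):
        ang = 2 * np.pi * k / params.n_roots + rng.normal(0, 0.25)
        x0 = disc[0] + disc_r * np.cos(ang)
        y0 = disc[1] + disc_r * np.sin(ang)
        xs.append(x0)
        ys.append(y0)
        radii.append(params.initial_width / 2)
        if max_depth >= 1:
            queue.append((x0, y0, ang, params.initial_width, 1))
    max_steps = int(1.1 * size)
    while queue:
        x, y, heading, width, depth = queue.pop()
        for _ in range(max_steps):
            heading += rng.normal(0.0, params.tortuosity)
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            if not (-2 <= x < size + 2 and -2 <= y < size + 2) or width < 0.8:
                break
            xs.append(x)
            ys.append(y)
            radii.append(width / 2)
            width *= 0.9985  # slow taper along the branch
            if depth < max_depth and rng.random() < params.branch_prob:
                side = 1 if rng.random() < 0.5 else -1
                child_ang = heading + side * rng.uniform(0.35, 0.9)
                queue.append((x, y, child_ang, width * params.width_decay, depth + 1))
                heading -= side * rng.uniform(0.05, 0.25)
    return _render_discs(size, xs, ys, radii)


def generate_vessel_tree(params: VesselTreeParams | None = None) -> np.ndarray:
    """Generate a binary vessel-tree mask.

    Deterministic for a given seed. If a parameter combination lands outside
    the foreground-density band the tree is regrown with the branching depth
    adjusted (deeper when too sparse, shallower when too dense); after 10
    failed attempts a :class:`GenerationError` is raised.
    """
    params = params or VesselTreeParams()
    lo, hi = DENSITY_BAND
    depth = params.max_depth
    for attempt in range(10):
        mask = _grow_tree(params, depth, attempt)
        frac = float(mask.mean())
        if lo <= frac <= hi:
            return mask
        if frac < lo:
            # regrow deeper (never beyond the requested maximum) and reroll
            depth = min(depth + 1, params.max_depth)
        else:
            depth = max(depth - 1, 0)
    raise GenerationError(
        f"could not reach foreground fraction in [{lo}, {hi}] "
        f"after 10 attempts (last: {frac:.4f})"
    )


def add_occlusion(
    mask: np.ndarray,
    angle: float,
    width_px: float,
    fraction_target: float,
) -> np.ndarray:
    """Zero out foreground under a straight instrument-shaped band.

    The band runs along ``angle`` (radians) with thickness ``width_px``; its
    offset is chosen so that the removed fraction of foreground pixels is as
    close as possible to ``fraction_target`` (within +/-0.05 when reachable).
    Foreground is only ever removed, never added. If the band is too narrow
    to reach the target, the best-achievable offset is used and a warning is
    issued.
    """
    if not 0.0 <= fraction_target <= 0.5:
        raise ParameterError("fraction_target must be in [0, 0.5]")
    out = np.asarray(mask, dtype=np.uint8).copy()
    if width_px <= 0 or fraction_target == 0:
        return out
    ys, xs = np.nonzero(out)
    total = len(xs)
    if total == 0:
        return out
    # Signed distance of each foreground pixel from a line through the image
    # center along `angle`; the band keeps |proj - c| <= width/2.
    h, w = out.shape
    nx, ny = -np.sin(angle), np.cos(angle)
    proj = (xs - w / 2.0) * nx + (ys - h / 2.0) * ny
    order = np.sort(proj)
    half = width_px / 2.0
    # For each candidate band center (each pixel's projection), count pixels
    # inside the band with two binary searches.
    lo_idx = np.searchsorted(order, order - half, side="left")
    hi_idx = np.searchsorted(order, order + half, side="right")
    counts = hi_idx - lo_idx
    fracs = counts / total
    best = int(np.argmin(np.abs(fracs - fraction_target)))
    achieved = float(fracs[best])
    if abs(achieved - fraction_target) > 0.05:
        warnings.warn(
            f"occlusion band of width {width_px} px reaches fraction "
            f"{achieved:.3f}, not the target {fraction_target:.3f}",
            stacklevel=2,
        )
    c = order[best]
    out[ys[np.abs(proj - c) <= half], xs[np.abs(proj - c) <= half]] = 0
    return out


def make_fixture_pair(
    seed: int,
    theta: float = 0.0,
    scale: float = 1.0,
    d: tuple[float, float] = (0.0, 0.0),
    occlusion_fraction: float = 0.0,
    illumination: tuple[float, float] | None = None,
    params: VesselTreeParams | None = None,
) -> FixturePair:
    """Build a fixed/moving pair with ground-truth motion.

    ``moving`` is the generated tree warped by the similarity transform
    (rotation ``theta``, scale, translation ``d``, pivot = image center),
    then occluded. ``illumination`` = (gain, bias) produces a grayscale
    variant of the moving map (``moving_gray``); the binary maps are
    unaffected, since segmentation removes photometric variation before
    registration.
    """
    if scale <= 0:
        raise ParameterError("scale must be positive")
    if abs(theta) > np.pi / 2:
        raise ParameterError("|theta| must be <= pi/2")
    if occlusion_fraction >= 0.9:
        raise ParameterError(
            "occlusion_fraction >= 0.9 would leave the pair unregistrable"
        )
    params = params or VesselTreeParams(seed=seed)
    if params.seed != seed:
        params = replace(params, seed=seed)
    fixed = generate_vessel_tree(params)
    h, w = fixed.shape
    truth = SimilarityTransform.from_params(
        theta, scale, d, pivot=((w - 1) / 2.0, (h - 1) / 2.0)
    )
    moving = warp(fixed, truth, out_size=(w, h))
    if occlusion_fraction > 0:
        band_rng = np.random.default_rng([seed, 7])
        moving = add_occlusion(
            moving,
            angle=float(band_rng.uniform(0, np.pi)),
            width_px=0.12 * w,
            fraction_target=occlusion_fraction,
        )
    moving_gray = None
    if illumination is not None:
        gain, bias = illumination
        moving_gray = np.clip(gain * moving.astype(float) + bias, 0.0, 1.0)
    return FixturePair(
        fixed=fixed,
        moving=moving,
        truth=truth,
        occlusion_fraction=occlusion_fraction,
        moving_gray=moving_gray,
    )


def random_fixture(
    seed: int,
    theta_range_deg: tuple[float, float] = (-15.0, 15.0),
    scale_range: tuple[float, float] = (0.9, 1.1),
    max_shift: float = 20.0,
    occlusion_fraction: float = 0.0,
) -> FixturePair:
    """Draw a fixture with motion sampled uniformly from the given ranges.

    The default ranges are the operating envelope of intra-operative motion
    the registration algorithm is exercised against: |rotation| <= 15
    degrees, scale within 10%, translation up to 20 px at 256x256.
    """
    rng = np.random.default_rng([seed, 11])
    theta = np.deg2rad(rng.uniform(*theta_range_deg))
    s = rng.uniform(*scale_range)
    ang = rng.uniform(0, 2 * np.pi)
    r = rng.uniform(0, max_shift)
    return make_fixture_pair(
        seed,
        theta=float(theta),
        scale=float(s),
        d=(float(r * np.cos(ang)), float(r * np.sin(ang))),
        occlusion_fraction=occlusion_fraction,
    )


def reprojection_error(
    fixed: np.ndarray,
    estimated: SimilarityTransform,
    truth: SimilarityTransform,
    statistic: str = "mean",
) -> float:
    """Vessel-pixel reprojection error of an estimated transform.

    Maps every foreground pixel of ``fixed`` through both transforms and
    aggregates the Euclidean distances between the two images of each pixel
    (``statistic``: "mean" or "median"). This is the geometric registration
    error in pixels, independent of resampling.
    """
    ys, xs = np.nonzero(np.asarray(fixed))
    if len(xs) == 0:
        raise ParameterError("fixed mask has no foreground")
    pts = np.column_stack([xs, ys]).astype(float)
    d = np.linalg.norm(estimated.apply(pts) - truth.apply(pts), axis=1)
    if statistic == "mean":
        return float(d.mean())
    if statistic == "median":
        return float(np.median(d))
    raise ParameterError(f"unknown statistic {statistic!r}")
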