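"""Iterative patch-wise cross-correlation (IPCC) registration.

The algorithm aligns a pre-operative vessel map ``A`` onto an intra-operative
vessel map ``B`` the way a human would: pick a few distinctive regions of
``A``, find where they sit in ``B``, fit the rigid-plus-scale motion implied
by two such correspondences, apply it, and repeat until the estimate stops
moving.

Concretely, each iteration ``k``:

1. warps ``A`` by the accumulated transform ``T_{k-1}`` (``T_0`` = identity),
2. divides the warped map into an ``n x n`` patch grid,
3. correlates every sufficiently vesselled patch against ``B`` (Pearson
   normalized cross-correlation, :mod:`ipcc_ar.correlation`),
4. selects the two best-scoring, spatially separated matches ``p1``, ``p2``,
5. estimates a rotation-scaling ``T_rs,k`` about the corner of ``p1`` and a
   translation ``T_t,k`` from the corner displacement of ``p1``,
6. composes ``T_k = (T_t,k @ T_rs,k) @ T_{k-1}``,

stopping when the mean absolute element-wise relative change Δ of the
transform matrix falls below a tolerance, or after a fixed iteration cap
(default three — the estimate stabilizes by the third round).

The rotation angle comes from the two inter-patch displacement vectors
``a = C2A - C1A`` (reference side) and ``b = C2B - C1B`` (target side):

    theta = atan2(a x b, a . b),      s = |b| / |a|

which is the unique similarity consistent with the two correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform
from skimage.transform import warp as _skimage_warp

from .correlation import TargetCache, cross_correlate
from .errors import (
    DegenerateGeometryError,
    DegeneratePatchError,
    ParameterError,
    RegistrationError,
)
from .transform import SimilarityTransform

__all__ = [
    "PatchCell",
    "PatchGrid",
    "PatchMatch",
    "IPCCConfig",
    "IterationRecord",
    "RegistrationResult",
    "make_patch_grid",
    "select_patch_pair",
    "estimate_rotation_scaling",
    "estimate_translation",
    "relative_change",
    "warp",
    "ipcc_register",
]

#: Minimum patch side in pixels; smaller patches carry too little structure
#: to produce a trustworthy correlation peak.
MIN_PATCH_SIDE = 8

#: Matrix elements smaller than this in magnitude are excluded from Δ
#: (the homogeneous row contains exact zeros).
DELTA_ELEMENT_EPS = 1e-9


@dataclass(frozen=True)
class PatchCell:
    """One cell of the reference-image patch grid."""

    i: int  # row index in the grid
    j: int  # column index in the grid
    x: int  # top-left column in pixels
    y: int  # top-left row in pixels
    w: int
    h: int

    @property
    def center(self) -> tuple[float, float]:
        return self.x + self.w / 2.0, self.y + self.h / 2.0


@dataclass(frozen=True)
class PatchGrid:
    n: int
    patches: tuple[PatchCell, ...]


@dataclass(frozen=True)
class PatchMatch:
    """A grid patch with its best-correlation placement in the target.

    ``corner_A`` is the patch's top-left corner in the (warped) reference
    image; ``corner_B`` the matched window's top-left corner in the target
    (fractional when sub-pixel refinement is enabled); ``score`` the Pearson
    coefficient in [-1, 1].
    """

    patch: PatchCell
    corner_A: tuple[float, float]
    corner_B: tuple[float, float]
    score: float


@dataclass(frozen=True)
class IPCCConfig:
    """Tunable parameters of the registration loop.

    Attributes
    ----------
    n
        Grid order: the reference map is divided into ``n x n`` patches.
    t
        Correlation acceptance threshold; matches scoring <= ``t`` are
        ignored. Scale-free because scores are Pearson coefficients.
    max_iterations
        Iteration cap ``K_max``; the transform estimate stabilizes by the
        third iteration, which is the default.
    delta_tol
        Early-stop tolerance on Δ, the mean absolute element-wise relative
        change of the transform matrix between iterations.
    min_separation
        Minimum distance in pixels between the two selected patches' centers
        on the reference side; ``None`` means one patch diagonal. Guards the
        angle estimate against short baselines.
    match_blur_sigma
        Gaussian sigma (pixels) applied to both skeleton maps before
        correlation. Unit-width centerlines barely overlap under small
        misalignments; a mild blur widens the correlation peak's capture
        basin without moving it. 0 disables.
    subpixel
        Refine the integer arg-max of each correlation surface with a
        one-dimensional quadratic fit per axis (skipped when the peak is a
        perfect score, which is already exact).
    min_patch_density
        Patches whose foreground fraction on the reference side falls below
        this are skipped; near-blank patches have no matchable structure.
    peak_ratio
        Distinctiveness test: a patch is discarded when a secondary
        correlation peak further than ``peak_exclusion_radius`` from the
        primary scores more than ``peak_ratio`` times the primary. Patches
        lying along a single straight vessel correlate almost equally well at
        many placements; their best placement carries no information. ``None``
        disables the test.
    peak_exclusion_radius
        Half-width in pixels of the box around the primary peak ignored when
        searching for the secondary peak.
    max_incremental_rotation
        Plausibility bound (radians) on the rotation of a single iteration's
        incremental estimate; candidate patch pairs implying more are
        rejected and the next-best pair is tried. Intra-operative motion
        between a pre-operative map and a frame stays well inside this.
    incremental_scale_range
        Same plausibility bound for the incremental scale factor.
    """

    n: int = 4
    t: float = 0.3
    max_iterations: int = 3
    delta_tol: float = 0.01
    min_separation: float | None = None
    match_blur_sigma: float = 3.0
    subpixel: bool = True
    min_patch_density: float = 0.01
    peak_ratio: float | None = 0.9
    peak_exclusion_radius: int = 10
    max_incremental_rotation: float = np.deg2rad(30.0)
    incremental_scale_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("grid order n must be >= 1")
        if not -1.0 <= self.t <= 1.0:
            raise ParameterError("threshold t must be in [-1, 1]")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.delta_tol < 0:
            raise ParameterError("delta_tol must be >= 0")


@dataclass(frozen=True)
class IterationRecord:
    transform: SimilarityTransform  # accumulated T_k
    delta: float
    pair: tuple[PatchMatch, PatchMatch]


@dataclass(frozen=True)
class RegistrationResult:
    transform: SimilarityTransform  # final T_K
    iterations: tuple[IterationRecord, ...]
    converged: bool  # True iff the Δ tolerance stopped the loop

    @property
    def K(self) -> int:
        return len(self.iterations)

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(rec.delta for rec in self.iterations)


def make_patch_grid(image: np.ndarray, n: int) -> PatchGrid:
    """Divide an image into ``n x n`` equally sized cells.

    Cell size is ``(floor(w/n), floor(h/n))``; remainder pixels on the right
    and bottom edges are excluded. Cells below 8 px per side are rejected.
    """
    if n < 1:
        raise ParameterError("grid order n must be >= 1")
    h, w = np.asarray(image).shape[:2]
    pw, ph = w // n, h // n
    if pw < MIN_PATCH_SIDE or ph < MIN_PATCH_SIDE:
        raise ParameterError(
            f"{n}x{n} grid on a {w}x{h} image gives {pw}x{ph} patches; "
            f"minimum side is {MIN_PATCH_SIDE} px"
        )
    cells = tuple(
        PatchCell(i=i, j=j, x=j * pw, y=i * ph, w=pw, h=ph)
        for i in range(n)
        for j in range(n)
    )
    return PatchGrid(n=n, patches=cells)


def select_patch_pair(
    matches: list[PatchMatch], t: float, min_separation: float
) -> tuple[PatchMatch, PatchMatch]:
    """Pick the two best matches above threshold with a sufficient baseline.

    ``p1`` is the highest-scoring match with score > ``t``; ``p2`` is the
    highest-scoring remaining match whose reference-side patch center lies at
    least ``min_separation`` pixels from ``p1``'s. Score ties break on grid
    index (row-major).
    """
    eligible = sorted(
        (m for m in matches if m.score > t),
        key=lambda m: (-m.score, m.patch.i, m.patch.j),
    )
    if len(eligible) < 2:
        raise RegistrationError(
            f"{len(eligible)} match(es) above threshold t={t}; need 2"
        )
    p1 = eligible[0]
    c1 = np.array(p1.patch.center)
    for m in eligible[1:]:
        if np.hypot(*(np.array(m.patch.center) - c1)) >= min_separation:
            return p1, m
    raise RegistrationError(
        f"no second match >= {min_separation:.1f} px from the best match"
    )


def estimate_rotation_scaling(p1: PatchMatch, p2: PatchMatch) -> SimilarityTransform:
    """Rotation-scaling ``T_rs`` about ``p1``'s reference corner.

    With ``a = C2A - C1A`` and ``b = C2B - C1B``:
    ``theta = atan2(a x b, a . b)`` and ``s = |b| / |a|``; the matrix rotates
    and scales about the pivot ``(C1Ax, C1Ay)``, which maps to itself.
    """
    a = np.asarray(p2.corner_A, dtype=float) - np.asarray(p1.corner_A, dtype=float)
    b = np.asarray(p2.corner_B, dtype=float) - np.asarray(p1.corner_B, dtype=float)
    na, nb = np.hypot(*a), np.hypot(*b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError("correspondence points coincide")
    theta = float(np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b))
    s = float(nb / na)
    return SimilarityTransform.rotation_scaling(theta, s, pivot=tuple(p1.corner_A))


def estimate_translation(p1: PatchMatch) -> SimilarityTransform:
    """Pure translation ``T_t`` by the corner displacement of ``p1``."""
    return SimilarityTransform.translation(
        p1.corner_B[0] - p1.corner_A[0], p1.corner_B[1] - p1.corner_A[1]
    )


def relative_change(
    previous: SimilarityTransform, current: SimilarityTransform
) -> float:
    """Δ: mean absolute element-wise relative change between two transforms.

    Elements of the current matrix with magnitude below ``1e-9`` (the exact
    zeros of the homogeneous row, and any vanishing off-diagonal terms) are
    excluded from the mean, since a relative change against zero is
    undefined.
    """
    prev, cur = previous.matrix, current.matrix
    include = np.abs(cur) >= DELTA_ELEMENT_EPS
    if not include.any():
        raise DegenerateGeometryError("all matrix elements excluded from Δ")
    return float(
        np.mean(np.abs(prev[include] - cur[include]) / np.abs(cur[include]))
    )


def warp(
    image: np.ndarray,
    T: SimilarityTransform,
    out_size: tuple[int, int] | None = None,
    order: int | None = None,
) -> np.ndarray:
    """Resample ``image`` under ``T`` by inverse mapping.

    Float images are interpolated bilinearly, binary masks by nearest
    neighbor (override with ``order``). ``out_size`` is ``(width, height)``;
    samples falling outside the input are 0.
    """
    arr = np.asarray(image)
    is_binary = arr.dtype == np.uint8 or arr.dtype == bool
    if order is None:
        order = 0 if is_binary else 1
    h, w = arr.shape[:2]
    out_shape = (out_size[1], out_size[0]) if out_size is not None else (h, w)
    if np.allclose(T.matrix, np.eye(3)) and out_shape == (h, w):
        return arr.copy()
    inv = ProjectiveTransform(matrix=np.linalg.inv(T.matrix))
    warped = _skimage_warp(
        arr.astype(float),
        inverse_map=inv,
        output_shape=out_shape,
        order=order,
        cval=0.0,
        preserve_range=True,
    )
    if is_binary:
        return (warped >= 0.5).astype(np.uint8)
    return warped


def _subpixel_offset(surface: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Quadratic (three-point parabola) refinement of an interior arg-max."""

    def axis_offset(sm: float, s0: float, sp: float) -> float:
        denom = sm - 2.0 * s0 + sp
        if denom >= -1e-12:  # flat or non-concave: keep the integer peak
            return 0.0
        off = 0.5 * (sm - sp) / denom
        return float(np.clip(off, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < y < surface.shape[0] - 1:
        dy = axis_offset(surface[y - 1, x], surface[y, x], surface[y + 1, x])
    if 0 < x < surface.shape[1] - 1:
        dx = axis_offset(surface[y, x - 1], surface[y, x], surface[y, x + 1])
    return dx, dy


def _is_distinct_peak(
    surface: np.ndarray, y: int, x: int, score: float, ratio: float, radius: int
) -> bool:
    """True if no secondary peak outside a box around (x, y) rivals the primary."""
    masked = surface.copy()
    masked[
        max(y - radius, 0) : y + radius + 1, max(x - radius, 0) : x + radius + 1
    ] = -np.inf
    if not np.isfinite(masked).any():
        return True
    return float(masked.max()) <= ratio * score


def _match_patches(
    A_bin: np.ndarray,
    A_soft: np.ndarray,
    cache: TargetCache,
    grid: PatchGrid,
    config: IPCCConfig,
) -> list[PatchMatch]:
    matches: list[PatchMatch] = []
    for cell in grid.patches:
        sl = (slice(cell.y, cell.y + cell.h), slice(cell.x, cell.x + cell.w))
        if A_bin[sl].mean() < config.min_patch_density:
            continue
        try:
            surface, (bx, by, score) = cross_correlate(
                A_soft[sl], cache.target, cache=cache
            )
        except DegeneratePatchError:
            continue
        if config.peak_ratio is not None and not _is_distinct_peak(
            surface, by, bx, score, config.peak_ratio, config.peak_exclusion_radius
        ):
            continue
        fx, fy = float(bx), float(by)
        if config.subpixel and score < 1.0 - 1e-6:
            dx, dy = _subpixel_offset(surface, by, bx)
            fx, fy = bx + dx, by + dy
        matches.append(
            PatchMatch(
                patch=cell,
                corner_A=(float(cell.x), float(cell.y)),
                corner_B=(fx, fy),
                score=score,
            )
        )
    return matches


def _select_plausible_pair(
    matches: list[PatchMatch], min_sep: float, config: IPCCConfig
) -> tuple[PatchMatch, PatchMatch, SimilarityTransform]:
    """Best separated patch pair whose incremental estimate is plausible.

    Candidate pairs are tried in score order (the first candidate is exactly
    the :func:`select_patch_pair` choice); a pair is rejected when the
    similarity it implies rotates or rescales more in a single iteration than
    the configured plausibility bounds — such estimates come from a spurious
    match, and a lower-scoring pair is preferred over a wild transform.
    """
    eligible = sorted(
        (m for m in matches if m.score > config.t),
        key=lambda m: (-m.score, m.patch.i, m.patch.j),
    )
    if len(eligible) < 2:
        raise RegistrationError(
            f"{len(eligible)} match(es) above threshold t={config.t}; need 2"
        )
    s_lo, s_hi = config.incremental_scale_range
    for i, p1 in enumerate(eligible):
        c1 = np.array(p1.patch.center)
        for p2 in eligible[i + 1 :]:
            if np.hypot(*(np.array(p2.patch.center) - c1)) < min_sep:
                continue
            try:
                T_rs = estimate_rotation_scaling(p1, p2)
            except DegenerateGeometryError:
                continue
            if abs(T_rs.theta) > config.max_incremental_rotation:
                continue
            if not s_lo <= T_rs.scale <= s_hi:
                continue
            return p1, p2, T_rs
    raise RegistrationError("no plausible patch pair above threshold")


def ipcc_register(
    A: np.ndarray,
    B: np.ndarray,
    config: IPCCConfig | None = None,
    initial: SimilarityTransform | None = None,
) -> RegistrationResult:
    """Register skeletonized vessel map ``A`` onto ``B``.

    Parameters
    ----------
    A, B
        Skeletonized binary masks ({0, 1}). ``A`` is the pre-operative
        reference; ``B`` the intra-operative frame's map.
    config
        :class:`IPCCConfig`; defaults are the standard operating point
        (4x4 grid, t = 0.3, three iterations).
    initial
        Optional warm-start transform (e.g. the previous video frame's
        result); defaults to the identity.

    Returns
    -------
    RegistrationResult
        Final accumulated transform ``T_K`` mapping ``A``-coordinates to
        ``B``-coordinates, with per-iteration records.

    Raises
    ------
    RegistrationError
        If no eligible patch pair exists on the very first iteration; a
        stream-processing caller should fall back to the previous frame's
        transform. Failures on later iterations return the best transform so
        far with ``converged=False`` instead.
    """
    config = config or IPCCConfig()
    A = np.asarray(A)
    B = np.asarray(B)
    if A.ndim != 2 or B.ndim != 2:
        raise ParameterError("A and B must be 2-D binary masks")

    sigma = config.match_blur_sigma
    A_soft0 = gaussian_filter(A.astype(float), sigma) if sigma > 0 else A.astype(float)
    B_soft = gaussian_filter(B.astype(float), sigma) if sigma > 0 else B.astype(float)
    cache = TargetCache(B_soft)

    h, w = A.shape
    grid = make_patch_grid(A, config.n)
    cell = grid.patches[0]
    min_sep = (
        config.min_separation
        if config.min_separation is not None
        else float(np.hypot(cell.w, cell.h))
    )

    T = initial if initial is not None else SimilarityTransform.identity()
    records: list[IterationRecord] = []
    converged = False
    for _k in range(1, config.max_iterations + 1):
        A_bin_w = warp(A.astype(np.uint8), T, out_size=(w, h))
        A_soft_w = warp(A_soft0, T, out_size=(w, h))
        matches = _match_patches(A_bin_w, A_soft_w, cache, grid, config)
        try:
            p1, p2, T_rs = _select_plausible_pair(matches, min_sep, config)
        except (RegistrationError, DegenerateGeometryError) as exc:
            if not records:
                raise RegistrationError(
                    f"registration failed on the first iteration: {exc}"
                ) from exc
            break  # keep the best transform so far
        T_t = estimate_translation(p1)
        T_new = (T_t @ T_rs) @ T
        delta = relative_change(T, T_new)
        T = T_new
        records.append(IterationRecord(transform=T, delta=delta, pair=(p1, p2)))
        if delta < config.delta_tol:
            converged = True
            break

    return RegistrationResult(
        transform=T, iterations=tuple(records), converged=converged
    )
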