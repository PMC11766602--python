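"""Pearson-normalized cross-correlation of a patch against a target image.

The matching score between a patch ``P`` and an equally sized window of the
target is the Pearson correlation of their pixel values: both are mean-
centred and the dot product is normalized by the product of their standard
deviations. Scores therefore lie in [-1, 1] and a fixed acceptance threshold
is insensitive to illumination gain/bias — the property the registration
algorithm relies on when comparing coefficients across frames.

The full surface (one score per valid top-left placement) is computed with
an FFT cross-correlation for the numerator and integral images for the
window statistics; this is algebraically identical to the naive
per-placement Pearson scan and is verified against it in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from .errors import DegeneratePatchError, ParameterError

__all__ = ["cross_correlate", "TargetCache"]

#: Windows whose intensity standard deviation falls below this are scored 0.
_STD_EPS = 1e-7


class TargetCache:
    """Reusable FFT and integral-image products of a fixed target.

    One registration correlates many patches (and many iterations) against
    the same intra-operative map; caching the target transform ~halves the
    per-patch cost. Passing a cache never changes the result.
    """

    def __init__(self, target: np.ndarray):
        self.target = np.ascontiguousarray(target, dtype=float)
        ii = np.zeros((target.shape[0] + 1, target.shape[1] + 1))
        ii[1:, 1:] = self.target.cumsum(0).cumsum(1)
        ii2 = np.zeros_like(ii)
        ii2[1:, 1:] = (self.target**2).cumsum(0).cumsum(1)
        self._integral = ii
        self._integral_sq = ii2
        self._fft: dict[tuple[int, int], np.ndarray] = {}

    def target_fft(self, fshape: tuple[int, int]) -> np.ndarray:
        if fshape not in self._fft:
            self._fft[fshape] = rfft2(self.target, fshape)
        return self._fft[fshape]

    def window_sums(self, ph: int, pw: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-placement window sum and sum of squares."""
        ii, ii2 = self._integral, self._integral_sq
        s = ii[ph:, pw:] - ii[:-ph, pw:] - ii[ph:, :-pw] + ii[:-ph, :-pw]
        s2 = ii2[ph:, pw:] - ii2[:-ph, pw:] - ii2[ph:, :-pw] + ii2[:-ph, :-pw]
        return s, s2


def cross_correlate(
    patch: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray | None = None,
    cache: TargetCache | None = None,
) -> tuple[np.ndarray, tuple[int, int, float]]:
    """Correlate ``patch`` against every placement in ``target``.

    Parameters
    ----------
    patch, target
        2-D float arrays; the patch must be strictly smaller than the target
        in both dimensions.
    mask
        Optional validity mask over ``target`` pixels (1 = usable). Window
        placements in which more than half of the pixels are masked out
        (e.g. occluded by an instrument) are scored 0.
    cache
        Optional :class:`TargetCache` built on ``target``.

    Returns
    -------
    surface
        Array of shape ``(H - ph + 1, W - pw + 1)``; ``surface[y, x]`` is the
        Pearson correlation of the patch with the window whose top-left
        corner is ``(x, y)``. Zero-variance windows score 0.
    best
        ``(x, y, score)`` of the arg-max placement; ties resolve to the
        smallest ``y`` then smallest ``x``.

    Raises
    ------
    DegeneratePatchError
        If the patch has (numerically) zero intensity variance — the caller
        is expected to skip such patches.
    """
    p = np.asarray(patch, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if p.ndim != 2 or tgt.ndim != 2:
        raise ParameterError("patch and target must be 2-D")
    ph, pw = p.shape
    H, W = tgt.shape
    if ph >= H or pw >= W:
        raise ParameterError(
            f"patch {p.shape} must be strictly smaller than target {tgt.shape}"
        )

    p0 = p - p.mean()
    p_norm = float(np.sqrt((p0**2).sum()))
    if p_norm < _STD_EPS:
        raise DegeneratePatchError("patch has zero intensity variance")

    if cache is None:
        cache = TargetCache(tgt)
    fshape = (next_fast_len(H + ph - 1), next_fast_len(W + pw - 1))
    fp = rfft2(p0[::-1, ::-1], fshape)
    full = irfft2(cache.target_fft(fshape) * fp, fshape)
    # valid placements: window fully inside the target
    num = full[ph - 1 : H, pw - 1 : W]

    s, s2 = cache.window_sums(ph, pw)
    win_var = np.maximum(s2 - s * s / (ph * pw), 0.0)
    denom = np.sqrt(win_var) * p_norm
    ok = np.sqrt(win_var) > _STD_EPS
    surface = np.zeros_like(num)
    np.divide(num, denom, out=surface, where=ok)
    np.clip(surface, -1.0, 1.0, out=surface)

    if mask is not None:
        m = np.asarray(mask, dtype=float)
        if m.shape != tgt.shape:
            raise ParameterError("mask must have the target's shape")
        mi = np.zeros((H + 1, W + 1))
        mi[1:, 1:] = m.cumsum(0).cumsum(1)
        valid = mi[ph:, pw:] - mi[:-ph, pw:] - mi[ph:, :-pw] + mi[:-ph, :-pw]
        surface[valid < 0.5 * ph * pw] = 0.0

    flat = int(np.argmax(surface))  # row-major argmax = smallest y, then x
    by, bx = divmod(flat, surface.shape[1])
    return surface, (int(bx), int(by), float(surface[by, bx]))
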