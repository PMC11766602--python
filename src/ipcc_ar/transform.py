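"""Homogeneous similarity transforms (rotation + uniform scale + translation).

Coordinates follow the raster convention used throughout the package:
``x`` = column, ``y`` = row, origin at the top-left pixel, 0-based. Matrices
act on column vectors ``[x, y, 1]^T`` and map reference-image (pre-operative)
coordinates into moving-image (intra-operative frame) coordinates. A positive
angle rotates from +x toward +y, i.e. clockwise on screen with y pointing
down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["SimilarityTransform"]


@dataclass(frozen=True)
class SimilarityTransform:
    """A 3x3 homogeneous similarity transform.

    The transform factors as a rotation by ``theta`` scaled by ``s`` about a
    pivot point, followed by a translation; the registration core builds it
    from two patch correspondences as ``T = T_t @ T_rs``.

    Parameters
    ----------
    matrix
        3x3 homogeneous matrix, bottom row exactly ``[0, 0, 1]``, with the
        upper-left 2x2 block a scaled rotation (determinant ``s**2 > 0``).
    pivot
        The ``(x, y)`` point the rotation-scaling part was anchored at.
        Informational; the matrix alone defines the mapping.
    """

    matrix: np.ndarray
    pivot: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ParameterError(f"matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ParameterError("matrix contains non-finite elements")
        if not np.array_equal(m[2], [0.0, 0.0, 1.0]):
            raise ParameterError("bottom row must be exactly [0, 0, 1]")
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if det <= 0:
            raise ParameterError(
                f"upper 2x2 determinant must be positive (s^2), got {det}"
            )
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "SimilarityTransform":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls(m)

    @classmethod
    def rotation_scaling(
        cls, theta: float, s: float, pivot: tuple[float, float] = (0.0, 0.0)
    ) -> "SimilarityTransform":
        """Rotation by ``theta`` (radians, y-down) scaled by ``s`` about ``pivot``.

        The pivot maps to itself: the translation column is
        ``pivot - s*R(theta) @ pivot``.
        """
        if s <= 0:
            raise ParameterError(f"scale must be positive, got {s}")
        c, sn = s * np.cos(theta), s * np.sin(theta)
        px, py = pivot
        m = np.array(
            [
                [c, -sn, px - c * px + sn * py],
                [sn, c, py - sn * px - c * py],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(m, pivot=(float(px), float(py)))

    @classmethod
    def from_params(
        cls,
        theta: float,
        s: float,
        translation: tuple[float, float] = (0.0, 0.0),
        pivot: tuple[float, float] = (0.0, 0.0),
    ) -> "SimilarityTransform":
        """Rotation-scaling about ``pivot`` followed by a translation."""
        t = cls.translation(*translation) @ cls.rotation_scaling(theta, s, pivot)
        return cls(t.matrix, pivot=(float(pivot[0]), float(pivot[1])))

    # -- derived scalars ---------------------------------------------------

    @property
    def theta(self) -> float:
        """Rotation angle in radians (positive = clockwise on screen)."""
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def scale(self) -> float:
        """Uniform scale factor ``s`` (> 0)."""
        m = self.matrix
        return float(np.sqrt(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]))

    @property
    def translation_vector(self) -> tuple[float, float]:
        return float(self.matrix[0, 2]), float(self.matrix[1, 2])

    # -- algebra -----------------------------------------------------------

    def __matmul__(self, other: "SimilarityTransform") -> "SimilarityTransform":
        if not isinstance(other, SimilarityTransform):
            return NotImplemented
        return SimilarityTransform(self.matrix @ other.matrix, pivot=self.pivot)

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform(np.linalg.inv(self.matrix), pivot=self.pivot)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(N, 2)`` array of ``(x, y)`` points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        return out[:, :2]

    def is_close(self, other: "SimilarityTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "theta_rad": self.theta,
            "scale": self.scale,
            "pivot": [self.pivot[0], self.pivot[1]],
        }

    def to_json(self, **extra) -> str:
        d = self.to_dict()
        d.update(extra)
        return json.dumps(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        pivot = tuple(d.get("pivot", (0.0, 0.0)))
        return cls(np.asarray(d["matrix"], dtype=float), pivot=pivot)

    @classmethod
    def from_json(cls, s: str) -> "SimilarityTransform":
        return cls.from_dict(json.loads(s))
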