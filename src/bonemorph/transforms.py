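"""Planar similarity transforms shared by the phantom generator and registration.

A similarity transform maps a point ``p = (x, y)`` (x = column, y = row,
both in pixels, 0-based, row index increasing downward) to

    p' = s * R(theta) @ p + t

with isotropic scale ``s > 0``, rotation ``theta`` (counter-clockwise in the
x-right / y-down raster frame) and translation ``t = (dx, dy)``.  Reflections
are deliberately not representable: slides are never flipped between the
mineral scan and the TRAP/AP scans, only rotated, shifted and (through tape
shrinkage) mildly rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktf

__all__ = ["SimilarityTransform"]


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation / isotropic-scale / translation map between two scans.

    Parameters
    ----------
    rotation_deg : float
        Counter-clockwise rotation in degrees (raster frame).
    scale : float
        Isotropic scale factor, strictly positive.
    dx, dy : float
        Translation in pixels along columns (x) and rows (y).
    rmse_px : float
        Residual of the least-squares fit that produced this transform,
        in pixels; 0.0 for exactly specified transforms.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    dx: float = 0.0
    dy: float = 0.0
    rmse_px: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.rmse_px < 0:
            raise ValueError("rmse_px must be >= 0")

    # ------------------------------------------------------------------ algebra
    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array(
            [
                [self.scale * c, -self.scale * s, self.dx],
                [self.scale * s, self.scale * c, self.dy],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, rmse_px: float = 0.0) -> "SimilarityTransform":
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rot = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
        return cls(rotation_deg=rot, scale=scale, dx=float(m[0, 2]), dy=float(m[1, 2]), rmse_px=rmse_px)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)

    @classmethod
    def about_center(
        cls,
        rotation_deg: float,
        scale: float,
        shift: tuple[float, float],
        shape: tuple[int, int],
    ) -> "SimilarityTransform":
        """Rotation+scale about the image center followed by a pixel shift.

        ``shape`` is (rows, cols); ``shift`` is (dx, dy).  This is the natural
        parameterization of a slide that was lifted, restained and replaced.
        """
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        base = cls(rotation_deg=rotation_deg, scale=scale)
        # T(+c) . S . T(-c) . then extra shift
        p = base.apply(np.array([[-cx, -cy]]))[0]
        dx = p[0] + cx + shift[0]
        dy = p[1] + cy + shift[1]
        return cls(rotation_deg=rotation_deg, scale=scale, dx=dx, dy=dy)

    def to_skimage(self) -> sktf.SimilarityTransform:
        return sktf.SimilarityTransform(matrix=self.matrix)

    # ------------------------------------------------------------------ I/O
    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation_deg": self.rotation_deg,
                "scale": self.scale,
                "dx": self.dx,
                "dy": self.dy,
                "rmse_px": self.rmse_px,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SimilarityTransform":
        d = json.loads(text)
        return cls(**d)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.rotation_deg) <= tol
            and abs(self.scale - 1.0) <= tol
            and abs(self.dx) <= tol
            and abs(self.dy) <= tol
        )
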