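"""Stitching of overlapping fractional scans by k-th law nonlinear correlation.

The microscope scans a whole section as a grid of tiles with 10-15 % overlap.
Pairwise translations between adjacent tiles are found from the inverse FFT of
the cross-power spectrum whose magnitude is raised to an exponent k in [0, 1]:
k = 0 is pure phase correlation (only phase information), k = 1 weights by the
full spectral magnitude (classical cross-correlation); the working default
k = 0.3 balances intensity against phase information.  Offsets are integer
pixels — stitching to one pixel is far below any measured structure — and
global tile placements are chained row-then-column from the pairwise offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import RasterImage
from .phantom import TileGrid

__all__ = [
    "Translation",
    "kth_law_correlate",
    "estimate_overlap_offset",
    "assemble_tiles",
    "DEFAULT_K",
]

log = logging.getLogger(__name__)

DEFAULT_K = 0.3

#: spectral magnitude floor before exponentiation, guards zero-energy bins
_EPS = 1e-12


@dataclass(frozen=True)
class Translation:
    """Integer pixel shift of one tile relative to another, with QC score."""

    dy: int
    dx: int
    peak_score: float


class DegenerateImageError(ValueError):
    """Raised when a correlation input carries no structure."""


def _as_float(img: RasterImage | np.ndarray) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.astype_float()
    return np.asarray(img, dtype=float)


def kth_law_correlate(a, b, k: float = DEFAULT_K) -> np.ndarray:
    """Correlation surface of ``b`` against ``a``; argmax = shift taking a to b.

    Computes ifft2( C * |C|^(k-1) ) with C = F(b) * conj(F(a)), i.e. the
    cross-power spectrum with its magnitude raised to the power k.  A peak at
    (dy, dx) means ``a`` cyclically shifted by (dy, dx) best matches ``b``.
    """
    a = _as_float(a)
    b = _as_float(b)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must be in [0, 1], got {k}")
    if not a.any() or not b.any():
        raise DegenerateImageError("all-zero input: correlation surface is flat")
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    if np.all(mag <= _EPS):
        raise DegenerateImageError("structureless input: cross-power spectrum is empty")
    weighted = cross * (np.maximum(mag, _EPS) ** (k - 1.0))
    surf = np.real(np.fft.ifft2(weighted))
    return surf


def peak_shift(surface: np.ndarray) -> Translation:
    """Argmax of a correlation surface, wrap-around resolved to the signed
    shift of smallest magnitude."""
    idx = np.unravel_index(np.argmax(surface), surface.shape)
    dy, dx = int(idx[0]), int(idx[1])
    nr, nc = surface.shape
    if dy > nr // 2:
        dy -= nr
    if dx > nc // 2:
        dx -= nc
    return Translation(dy=dy, dx=dx, peak_score=float(surface[idx]))


def estimate_overlap_offset(
    left: RasterImage,
    right: RasterImage,
    k: float = DEFAULT_K,
    expected_overlap: float = 0.15,
    axis: int = 1,
    min_peak_score: float = 0.01,
) -> Translation:
    """Offset of ``right`` relative to ``left`` for two adjacent tiles.

    ``axis=1`` means right neighbours (offset mostly in columns), ``axis=0``
    top/bottom neighbours.  The peak search is restricted to the window of
    overlaps between half and double the expected one (capped at 50 %); a
    peak whose quality (relative to the attainable spectral bound) falls
    below ``min_peak_score`` raises: no reliable overlap.
    """
    if not 0.05 <= expected_overlap <= 0.5:
        raise ValueError(f"expected_overlap must be in [0.05, 0.5], got {expected_overlap}")
    a = _as_float(left)
    b = _as_float(right)
    surf = kth_law_correlate(a, b, k)
    nr, nc = surf.shape
    size = nc if axis == 1 else nr
    ov_lo = 0.5 * expected_overlap * size
    ov_hi = min(2.0 * expected_overlap, 0.5) * size
    lo = int(np.floor(size - ov_hi))
    hi = int(np.ceil(size - ov_lo))
    # candidate along-axis placements (right/bottom tile sits `size - overlap`
    # pixels ahead of its neighbour); cross-axis jitter of +/- 10 % of the tile.
    # The placement (dy, dx) of `right` corresponds to the correlation peak at
    # the negated shift: right tile content = left content `placement` ahead.
    jitter = max(2, int(round(0.1 * (nr if axis == 1 else nc))))
    best = None
    for main in range(lo, hi + 1):
        for cross in range(-jitter, jitter + 1):
            dy, dx = (cross, main) if axis == 1 else (main, cross)
            score = surf[(-dy) % nr, (-dx) % nc]
            if best is None or score > best[0]:
                best = (score, dy, dx)
    assert best is not None
    # attainable upper bound of the weighted inverse transform: all phases aligned
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    mag = np.abs(fb * np.conj(fa))
    bound = float(np.mean(np.maximum(mag, _EPS) ** k))
    quality = best[0] / bound if bound > 0 else 0.0
    if quality < min_peak_score:
        raise DegenerateImageError(
            f"no reliable overlap: peak quality {quality:.3g} below floor {min_peak_score:g}"
        )
    return Translation(dy=int(best[1]), dx=int(best[2]), peak_score=float(quality))


def _check_degenerate(grid: TileGrid) -> None:
    for i, row in enumerate(grid.tiles):
        for j, tile in enumerate(row):
            if np.ptp(tile.pixels) == 0:
                raise DegenerateImageError(f"tile ({i}, {j}) is structureless (constant)")


def assemble_tiles(grid: TileGrid, k: float = DEFAULT_K) -> tuple[RasterImage, np.ndarray]:
    """Stitch a tile grid into one raster; returns (image, placements).

    Pairwise offsets are chained row-then-column into global placements;
    where chains disagree at a tile (loop closure), a discrepancy above 2 px
    logs a warning and above 10 px raises.  Overlap pixels keep the first
    placed tile's values (row-major placement order).
    """
    nrows, ncols = grid.grid_shape
    th, tw = grid.tile_shape
    if nrows == 1 and ncols == 1:
        tile = grid.tiles[0][0]
        return tile.with_pixels(tile.pixels.copy()), np.zeros((1, 1, 2), dtype=int)
    _check_degenerate(grid)

    ov = grid.nominal_overlap
    pos = np.zeros((nrows, ncols, 2), dtype=int)
    # first column: chain downward
    for i in range(1, nrows):
        t = estimate_overlap_offset(grid.tiles[i - 1][0], grid.tiles[i][0], k, ov, axis=0)
        pos[i, 0] = pos[i - 1, 0] + (t.dy, t.dx)
    # each row: chain rightward
    for i in range(nrows):
        for j in range(1, ncols):
            t = estimate_overlap_offset(grid.tiles[i][j - 1], grid.tiles[i][j], k, ov, axis=1)
            pos[i, j] = pos[i, j - 1] + (t.dy, t.dx)
    # loop closure: recompute second row onwards via the column chain
    for i in range(1, nrows):
        for j in range(1, ncols):
            t = estimate_overlap_offset(grid.tiles[i - 1][j], grid.tiles[i][j], k, ov, axis=0)
            alt = pos[i - 1, j] + (t.dy, t.dx)
            gap = np.abs(alt - pos[i, j]).max()
            if gap > 10:
                raise ValueError(
                    f"loop closure failed at tile ({i}, {j}): chains disagree by {gap} px"
                )
            if gap > 2:
                log.warning(
                    "loop closure discrepancy %d px at tile (%d, %d); keeping row chain",
                    gap,
                    i,
                    j,
                )

    pos -= pos.reshape(-1, 2).min(axis=0)
    out_h = int(pos[..., 0].max()) + th
    out_w = int(pos[..., 1].max()) + tw
    canvas = np.zeros((out_h, out_w), dtype=float)
    filled = np.zeros((out_h, out_w), dtype=bool)
    for i in range(nrows):
        for j in range(ncols):
            r, c = pos[i, j]
            sub = canvas[r : r + th, c : c + tw]
            subf = filled[r : r + th, c : c + tw]
            fresh = ~subf
            sub[fresh] = grid.tiles[i][j].astype_float()[fresh]
            subf |= True
    px = grid.tiles[0][0].pixel_size_um
    return RasterImage(canvas, px), pos
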