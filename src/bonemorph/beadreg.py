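"""Fiducial-bead registration of the TRAP / AP scans to the mineral reference.

The TRAP and AP stains happen off the scanning stage, so those scans come
back rotated, shifted and mildly rescaled (tape shrinkage).  Monodisperse
6 µm fluorescent beads spotted next to the bone matrix appear in both the
reference (label) channels and the restained scans; matching their centroids
gives a closed-form least-squares similarity transform (rotation, isotropic
scale, translation — no reflection, slides are never flipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage import transform as sktf

from .image_io import ChannelStack, RasterImage
from .segmentation import otsu_threshold
from .transforms import SimilarityTransform

__all__ = [
    "BeadSet",
    "detect_beads",
    "match_beads",
    "estimate_similarity",
    "warp_to_reference",
    "register_stack",
]

log = logging.getLogger(__name__)


@dataclass
class BeadSet:
    """Detected fiducial beads: (x, y) centroids and equivalent diameters."""

    centroids: np.ndarray  # (N, 2) of (x, y) px
    diameters_um: np.ndarray  # (N,)
    channel_role: str = ""

    def __len__(self) -> int:
        return len(self.centroids)


class InsufficientFiducialsError(ValueError):
    pass


def detect_beads(
    image: RasterImage,
    expected_diameter_um: float = 6.0,
    channel_role: str = "",
    solidity_min: float = 0.8,
) -> BeadSet:
    """Find bright disk-like components within +/-50 % of the expected diameter.

    Centroids are intensity-weighted; an empty set is a valid result (the
    caller decides whether enough fiducials were found).
    """
    exp_px = expected_diameter_um / image.pixel_size_um
    if exp_px <= 2:
        raise ValueError(
            f"expected bead diameter {expected_diameter_um} um is only {exp_px:.1f} px "
            "at this pixel size; beads are unresolvable"
        )
    arr = image.astype_float()
    if np.ptp(arr) == 0:
        return BeadSet(np.empty((0, 2)), np.empty(0), channel_role)
    thr = otsu_threshold(arr.ravel())
    mask = arr > thr
    labels, _ = ndimage.label(mask)
    nr, nc = arr.shape
    cents, diams = [], []
    for prop in measure.regionprops(labels, intensity_image=arr):
        # resampling blurs bead rims; size/shape gates act on the half-max core
        core = prop.image & (prop.image_intensity >= thr + 0.5 * (prop.intensity_max - thr))
        n_core = int(core.sum())
        if n_core == 0:
            continue
        d_um = 2.0 * np.sqrt(n_core / np.pi) * image.pixel_size_um
        if not (0.5 * expected_diameter_um <= d_um <= 1.5 * expected_diameter_um):
            continue
        r0, c0, r1, c1 = prop.bbox
        if r0 == 0 or c0 == 0 or r1 == nr or c1 == nc:
            continue  # clipped at the field edge: centroid unreliable
        core_lbl = measure.label(core)
        core_props = measure.regionprops(core_lbl)
        if max(p.solidity for p in core_props) < solidity_min:
            continue
        weights = prop.image_intensity - thr
        weights[~prop.image] = 0.0
        rr, cc = np.mgrid[r0:r1, c0:c1]
        total = weights.sum()
        cents.append(((cc * weights).sum() / total, (rr * weights).sum() / total))
        diams.append(d_um)
    cents_arr = np.array(cents, dtype=float).reshape(-1, 2)
    return BeadSet(cents_arr, np.array(diams), channel_role)


def _principal_angle(pts: np.ndarray) -> float:
    """Orientation (radians) of the dominant axis of a centered point cloud."""
    c = pts - pts.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    ax = v[:, np.argmax(w)]
    return float(np.arctan2(ax[1], ax[0]))


def _mutual_nearest(ref: np.ndarray, mov_aligned: np.ndarray) -> list[tuple[int, int]]:
    d = np.linalg.norm(ref[:, None, :] - mov_aligned[None, :, :], axis=2)
    pairs = []
    for i in range(len(ref)):
        j = int(np.argmin(d[i]))
        if int(np.argmin(d[:, j])) == i:
            pairs.append((i, j))
    return pairs


def match_beads(reference: BeadSet, moving: BeadSet) -> list[tuple[int, int]]:
    """Correspondences (ref index, moving index) by mutual nearest neighbours
    after coarse principal-axis alignment of the two centroid clouds.

    The principal axis is only defined up to 180 deg, so both candidate
    rotations are tried and the one yielding the tighter pairing wins.
    Unmatched beads are dropped; fewer than 2 pairs is an error.
    """
    if len(reference) < 2 or len(moving) < 2:
        raise InsufficientFiducialsError(
            f"need >= 2 beads in each set, got {len(reference)} and {len(moving)}"
        )
    ref = reference.centroids
    mov = moving.centroids
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    # scale-normalize by RMS radius
    s_ref = np.sqrt(np.mean(np.sum(ref_c**2, axis=1))) or 1.0
    s_mov = np.sqrt(np.mean(np.sum(mov_c**2, axis=1))) or 1.0
    # candidate coarse rotations: slides are replaced within +/- 30 deg, but
    # the principal axis of a near-isotropic bead cloud is unstable, so both
    # the axis-difference candidates and the no-rotation candidate are tried
    # and judged by the residual of the similarity actually fitted to the
    # resulting pairing (with its plausibility)
    base = _principal_angle(ref) - _principal_angle(mov)
    best: tuple[tuple, list[tuple[int, int]]] | None = None
    for th in {0.0, base, base + np.pi, base - np.pi}:
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        aligned = (mov_c / s_mov) @ rot.T * s_ref
        pairs = _mutual_nearest(ref_c, aligned)
        if len(pairs) < 2:
            continue
        try:
            tf = estimate_similarity(
                ref[[i for i, _ in pairs]], mov[[j for _, j in pairs]]
            )
        except ValueError:
            continue
        implausible = not (0.85 <= tf.scale <= 1.15) or abs(tf.rotation_deg) > 32.0
        key = (implausible, -len(pairs), tf.rmse_px)
        if best is None or key < best[0]:
            best = (key, pairs)
    if best is None:
        raise InsufficientFiducialsError("insufficient fiducials: fewer than 2 mutual pairs")
    return best[1]


def estimate_similarity(
    ref_points: np.ndarray, mov_points: np.ndarray
) -> SimilarityTransform:
    """Least-squares similarity mapping reference points onto moving points.

    Returns the transform S with mov ~= S(ref) — i.e. the motion the restained
    slide underwent — so that warping the moving scan with S recovers the
    reference frame.  Requires >= 2 non-coincident pairs; below 3 beads a QC
    warning is logged (the fit is then exact and unchecked).
    """
    ref_points = np.asarray(ref_points, dtype=float).reshape(-1, 2)
    mov_points = np.asarray(mov_points, dtype=float).reshape(-1, 2)
    if len(ref_points) != len(mov_points) or len(ref_points) < 2:
        raise InsufficientFiducialsError("need >= 2 point pairs")
    if len(np.unique(np.round(ref_points, 6), axis=0)) < 2:
        raise ValueError("degenerate fiducial cloud: fewer than 2 distinct points")
    if len(ref_points) < 3:
        log.warning("similarity estimated from only %d bead pairs", len(ref_points))
    if hasattr(sktf.SimilarityTransform, "from_estimate"):
        tf = sktf.SimilarityTransform.from_estimate(ref_points, mov_points)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity estimation failed (degenerate fiducial cloud)")
    else:  # older scikit-image
        tf = sktf.SimilarityTransform()
        if not tf.estimate(ref_points, mov_points) or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity estimation failed (degenerate fiducial cloud)")
    scale = float(np.hypot(tf.params[0, 0], tf.params[1, 0]))
    if scale <= 1e-9:
        # a mirrored correspondence has no proper-rotation similarity: the
        # reflection-free least squares collapses to zero scale
        raise ValueError("degenerate fit: no reflection-free similarity exists")
    pred = tf(ref_points)
    rmse = float(np.sqrt(np.mean(np.sum((pred - mov_points) ** 2, axis=1))))
    return SimilarityTransform.from_matrix(tf.params, rmse_px=rmse)


def warp_to_reference(
    stack: ChannelStack,
    transform: SimilarityTransform,
    channels: tuple[str, ...] = ("trap", "ap"),
) -> tuple[ChannelStack, np.ndarray]:
    """Resample the moving channels onto the reference grid (bilinear).

    ``transform`` maps reference coordinates to moving coordinates (the
    estimate from :func:`estimate_similarity`).  Out-of-field pixels are
    zero-filled and reported in the returned validity mask.
    """
    new = {}
    valid = np.ones(stack.shape, dtype=bool)
    if not transform.is_identity(tol=1e-9):
        nr, nc = stack.shape
        yy, xx = np.mgrid[0:nr, 0:nc]
        src = transform.apply(np.column_stack([xx.ravel(), yy.ravel()]))
        inside = (
            (src[:, 0] >= 0) & (src[:, 0] <= nc - 1) & (src[:, 1] >= 0) & (src[:, 1] <= nr - 1)
        )
        valid = inside.reshape(nr, nc)
    for role in channels:
        if role not in stack:
            continue
        img = stack[role]
        if transform.is_identity(tol=1e-9):
            new[role] = img.with_pixels(img.pixels.copy())
            continue
        warped = sktf.warp(
            img.astype_float(),
            inverse_map=transform.to_skimage(),
            order=1,
            mode="constant",
            cval=0.0,
            preserve_range=True,
        )
        warped[~valid] = 0.0
        new[role] = img.with_pixels(warped)
    return stack.replace(**new), valid


def register_stack(
    stack: ChannelStack,
    expected_bead_diameter_um: float = 6.0,
    moving_channels: tuple[str, ...] = ("trap", "ap"),
) -> tuple[ChannelStack, SimilarityTransform]:
    """End-to-end registration: detect beads on the label (reference) channels
    and on the moving channels, match, fit and warp."""
    ref_img = _combine(stack, ("label1", "label2"))
    mov_img = _combine(stack, moving_channels)
    ref_beads = detect_beads(ref_img, expected_bead_diameter_um, "label1+label2")
    mov_beads = detect_beads(mov_img, expected_bead_diameter_um, "+".join(moving_channels))
    if len(ref_beads) < 3 or len(mov_beads) < 3:
        log.warning(
            "few fiducials found: %d reference, %d moving", len(ref_beads), len(mov_beads)
        )
    pairs = match_beads(ref_beads, mov_beads)
    tf = estimate_similarity(
        ref_beads.centroids[[i for i, _ in pairs]],
        mov_beads.centroids[[j for _, j in pairs]],
    )
    if not (0.85 <= tf.scale <= 1.15) or abs(tf.rotation_deg) > 32.0:
        raise InsufficientFiducialsError(
            f"implausible fit (scale {tf.scale:.3f}, rotation {tf.rotation_deg:.1f} deg); "
            "refusing to warp"
        )
    warped, _ = warp_to_reference(stack, tf, moving_channels)
    return warped, tf


def _combine(stack: ChannelStack, roles: tuple[str, ...]) -> RasterImage:
    arrs = [stack[r].astype_float() for r in roles if r in stack]
    if not arrs:
        raise KeyError(f"none of {roles} present in stack")
    return RasterImage(np.maximum.reduce(arrs), stack.pixel_size_um)
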