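"""Iterative (cascaded) Otsu thresholding of the fluorescence channels.

A single Otsu threshold separates two intensity populations; scans of the
cell channels carry three — background outside the bone envelope, marrow
background inside it, and the actual TRAP / AP signal, which is brightest.
Re-running Otsu on the surviving foreground after each step isolates the
brightest population without being dominated by the global histogram: the
first pass discards the outside background, the second separates the marrow
background from the signal.

The threshold search uses a 256-bin histogram spanning the observed
min-max range regardless of camera bit depth, with ties broken toward the
lower threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .image_io import ChannelStack, RasterImage

__all__ = [
    "BinaryMask",
    "otsu_threshold",
    "iterative_otsu",
    "segment_channel",
    "DEFAULT_STEPS",
]

log = logging.getLogger(__name__)

N_BINS = 256
MIN_FOREGROUND_PX = 16

#: per-role default cascade depth: the mineral and label channels are
#: two-population (background vs signal), the cell stains carry the extra
#: marrow-background population
DEFAULT_STEPS = {
    "mineral": 1,
    "label1": 1,
    "label2": 1,
    "dapi": 1,
    "gfp": 1,
    "trap": 2,
    "ap": 2,
}


@dataclass
class BinaryMask:
    """Boolean signal mask with provenance."""

    pixels: np.ndarray
    pixel_size_um: float
    channel_role: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


class DegenerateHistogramError(ValueError):
    pass


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold of an intensity sample over a 256-bin histogram.

    Returns the bin boundary that maximizes the between-class variance
    (equivalently minimizes the intra-class variance); pixels strictly above
    the returned value are foreground.  Ties break toward the lower
    threshold.  Constant input raises.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateHistogramError("degenerate histogram: constant input")
    counts, edges = np.histogram(v, bins=N_BINS, range=(lo, hi))
    counts = counts.astype(float)
    total = counts.sum()
    p = counts / total
    omega = np.cumsum(p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    # between-class variance for threshold after bin t (t = 0..254)
    om = omega[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * om - mu[:-1]) ** 2 / (om * (1.0 - om))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    t = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximum
    return float(edges[t + 1])


def iterative_otsu(
    image: RasterImage | np.ndarray,
    steps: int = 1,
    within: Optional[BinaryMask] = None,
    channel_role: str = "",
) -> BinaryMask:
    """Cascade Otsu ``steps`` times, each pass re-thresholding the surviving
    foreground (the brighter class) only.

    Stops early with a warning if a step would leave fewer than 16 foreground
    pixels; the last valid mask is returned.  The result with ``steps`` s+1 is
    always a subset of the result with s steps.
    """
    if isinstance(image, RasterImage):
        arr = image.astype_float()
        px = image.pixel_size_um
    else:
        arr = np.asarray(image, dtype=float)
        px = 1.0
    if steps not in (1, 2, 3):
        raise ValueError(f"steps must be in {{1, 2, 3}}, got {steps}")
    current = np.ones(arr.shape, dtype=bool) if within is None else within.pixels.copy()
    if not current.any():
        raise ValueError("empty 'within' mask")
    for step in range(steps):
        sample = arr[current]
        if sample.max() == sample.min():
            if step == 0:
                raise DegenerateHistogramError("degenerate histogram: constant input")
            log.warning("iterative_otsu: constant foreground at step %d; stopping", step + 1)
            break
        thr = otsu_threshold(sample)
        nxt = current & (arr > thr)
        # later cascade steps refuse to collapse an already-thresholded mask;
        # the first threshold always applies
        if step > 0 and nxt.sum() < MIN_FOREGROUND_PX:
            log.warning(
                "iterative_otsu: step %d leaves %d px (< %d); returning previous mask",
                step + 1,
                int(nxt.sum()),
                MIN_FOREGROUND_PX,
            )
            break
        current = nxt
    return BinaryMask(current, px, channel_role)


def segment_channel(
    stack: ChannelStack,
    role: str,
    steps: Optional[int] = None,
    shade: Optional["ShadeParams"] = None,  # noqa: F821 - forward ref
) -> BinaryMask:
    """Threshold one channel with its per-role defaults.

    Mineral and label channels use a single Otsu pass, TRAP/AP two passes
    (marrow background).  ``steps`` overrides the default and is logged.
    """
    if role not in stack:
        raise KeyError(f"channel role {role!r} absent from stack")
    img = stack[role]
    if shade is not None:
        from .preprocess import shade_correct

        img = shade_correct(img, shade)
    n = DEFAULT_STEPS.get(role, 1) if steps is None else steps
    if steps is not None:
        log.info("segment_channel(%s): steps override = %d", role, steps)
    mask = iterative_otsu(img, steps=n, channel_role=role)
    # a first-pass all-foreground degenerate result (e.g. empty label channel
    # with pure noise) is handled by the caller via mask statistics
    return mask
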