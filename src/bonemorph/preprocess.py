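"""Shade correction: removal of slowly varying illumination background.

Inhomogeneous lighting or a misaligned camera leaves a gradual intensity
ramp across the assembled scan that confuses global thresholding.  The
correction subtracts a median-filtered copy of the image from itself; the
filter window must be larger than the largest trabecular feature, otherwise
bone structures are themselves erased by the subtraction.  As a side effect
the subtraction flattens minor background noise to ~0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import RasterImage

__all__ = ["ShadeParams", "shade_correct"]

log = logging.getLogger(__name__)

#: fallback window: 3x a conservative cortical-thickness estimate
DEFAULT_WINDOW_UM = 200.0 * 3


@dataclass(frozen=True)
class ShadeParams:
    """Median-filter background estimation parameters.

    ``window_um`` is the filter side length; ``max_feature_um`` is the
    configured size of the largest bone feature — a window not exceeding it
    triggers a misuse warning (bone would be subtracted away).
    """

    window_um: float = DEFAULT_WINDOW_UM
    max_feature_um: float | None = None

    def window_px(self, pixel_size_um: float) -> int:
        w = int(round(self.window_um / pixel_size_um))
        w = max(w, 3)
        if w % 2 == 0:
            w += 1
        return w


def _median_background(arr: np.ndarray, window: int) -> np.ndarray:
    """Median filter with reflective borders, fast for integer-valued data."""
    from skimage.filters import rank
    from skimage.morphology import footprint_rectangle

    pad = window // 2
    padded = np.pad(arr, pad, mode="reflect")
    # intensities are integer-valued camera counts; a uint16 rank filter is
    # exact for them and orders of magnitude faster than a sliding sort
    as_int = np.clip(np.rint(padded), 0, 65535).astype(np.uint16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        med = rank.median(as_int, footprint_rectangle((window, window)))
    return med[pad:-pad, pad:-pad].astype(float)


def shade_correct(image: RasterImage, params: ShadeParams | None = None) -> RasterImage:
    """Return clip(image - median_filter(image, window), 0, inf).

    Raises if the window reaches the image size; warns if it does not exceed
    the configured maximum feature size.
    """
    params = params or ShadeParams()
    window = params.window_px(image.pixel_size_um)
    nr, nc = image.shape
    if window >= min(nr, nc):
        raise ValueError(
            f"shade window {window} px must be smaller than the image {image.shape}"
        )
    if params.max_feature_um is not None and params.window_um <= params.max_feature_um:
        log.warning(
            "shade window %.0f um does not exceed the largest feature size %.0f um; "
            "bone structures may be attenuated",
            params.window_um,
            params.max_feature_um,
        )
    arr = image.astype_float()
    background = _median_background(arr, window)
    corrected = np.clip(arr - background, 0.0, None)
    return image.with_pixels(corrected)
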