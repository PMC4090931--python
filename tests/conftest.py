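"""Shared fixtures: phantoms and small geometric fixtures, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from bonemorph import phantom as ph
from bonemorph.image_io import RasterImage
from bonemorph.segmentation import BinaryMask


@pytest.fixture(scope="session")
def femur_phantom():
    """Default femur phantom: (spec, growth_plate_row, stack, truth)."""
    spec, gp = ph.femur_spec(seed=11)
    stack, truth = ph.make_trabecular_phantom(spec)
    return spec, gp, stack, truth


@pytest.fixture(scope="session")
def noiseless_femur_phantom():
    spec, gp = ph.femur_spec(seed=3, noise_sd=0.0)
    stack, truth = ph.make_trabecular_phantom(spec)
    return spec, gp, stack, truth


@pytest.fixture()
def textured_image():
    """A reproducible structured raster for correlation / stitching tests."""
    from scipy import ndimage

    rng = np.random.default_rng(42)
    # smoothed aperiodic noise: locally structured like tissue, no repeats
    base = 100.0 + 60.0 * ndimage.gaussian_filter(rng.normal(0, 1, (200, 200)), 3)
    base += rng.normal(0, 5, (200, 200))
    return RasterImage(np.clip(base, 0, None), pixel_size_um=2.0)


def stripe_bone(n: int = 200, width: int = 20, gap: int = 80, pixel_size_um: float = 2.0):
    """Periodic horizontal bone stripes as a BinaryMask (closed-form oracle)."""
    mask = np.zeros((n, n), dtype=bool)
    r = gap // 2
    while r + width <= n:
        mask[r : r + width] = True
        r += width + gap
    return BinaryMask(mask, pixel_size_um, "mineral")
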