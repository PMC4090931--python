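import numpy as np
import pytest

from bonemorph import beadreg, phantom as ph
from bonemorph.image_io import RasterImage
from bonemorph.transforms import SimilarityTransform


def bead_image(centers_xy, diameter_um=6.0, pixel_size_um=2.0, shape=(120, 120), value=1000.0):
    arr = np.full(shape, 30.0)
    r = diameter_um / 2.0 / pixel_size_um
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x, y in centers_xy:
        arr[(yy - y) ** 2 + (xx - x) ** 2 <= r**2] = value
    return RasterImage(arr, pixel_size_um)


def brute_force_similarity(ref, mov):
    """Exhaustive (rotation, scale) grid at 0.05 deg / 0.001 resolution;
    translation solved in closed form at each grid point."""
    best = None
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    for rot in np.arange(-10.0, 10.0001, 0.05):
        th = np.deg2rad(rot)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for scale in np.arange(0.95, 1.0501, 0.001):
            pred = scale * ref @ R.T
            t = (mov - pred).mean(axis=0)
            resid = float(np.sqrt(np.mean(np.sum((pred + t - mov) ** 2, axis=1))))
            if best is None or resid < best[0]:
                best = (resid, rot, scale, t)
    return best


# ------------------------------------------------------------------ detection


def test_detect_three_disks_within_half_pixel():
    centers = [(20.5, 30.5), (80.5, 25.5), (50.5, 90.5)]
    beads = beadreg.detect_beads(bead_image(centers), 6.0)
    assert len(beads) == 3
    got = beads.centroids[np.lexsort(beads.centroids.T)]
    want = np.array(sorted(centers, key=lambda c: (c[1], c[0])))
    assert np.all(np.linalg.norm(got - want, axis=1) <= 0.5)


def test_empty_image_gives_empty_set():
    img = RasterImage(np.full((50, 50), 30.0), 2.0)
    assert len(beadreg.detect_beads(img, 6.0)) == 0


def test_oversized_disk_excluded():
    img = bead_image([(60.5, 60.5)], diameter_um=20.0)
    assert len(beadreg.detect_beads(img, 6.0)) == 0


def test_unresolvable_bead_diameter_rejected():
    img = RasterImage(np.full((50, 50), 30.0), 4.0)
    with pytest.raises(ValueError, match="unresolvable"):
        beadreg.detect_beads(img, 6.0)


# ------------------------------------------------------------------ matching


def _bead_set(pts):
    pts = np.asarray(pts, float)
    return beadreg.BeadSet(pts, np.full(len(pts), 6.0))


def test_identical_sets_pair_identically():
    pts = [(10, 10), (50, 12), (30, 40), (70, 66)]
    pairs = beadreg.match_beads(_bead_set(pts), _bead_set(pts))
    assert sorted(pairs) == [(i, i) for i in range(4)]


def test_rotated_cloud_matches_truth_permutation():
    rng = np.random.default_rng(0)
    ref = rng.uniform(10, 100, (6, 2))
    t = SimilarityTransform(rotation_deg=5.0, scale=1.0, dx=3.0, dy=-2.0)
    perm = rng.permutation(6)
    mov = t.apply(ref)[perm]
    pairs = beadreg.match_beads(_bead_set(ref), _bead_set(mov))
    assert len(pairs) == 6
    assert all(perm[j] == i for i, j in pairs)


def test_unequal_cardinality_matches_the_smaller_set():
    rng = np.random.default_rng(1)
    ref = rng.uniform(10, 100, (5, 2))
    mov = ref[:3] + [1.0, 0.5]
    pairs = beadreg.match_beads(_bead_set(ref), _bead_set(mov))
    assert len(pairs) == 3


def test_too_few_beads_rejected():
    with pytest.raises(beadreg.InsufficientFiducialsError):
        beadreg.match_beads(_bead_set([(0, 0)]), _bead_set([(0, 0), (1, 1)]))


# ------------------------------------------------------------------ estimation


def test_aligned_pairs_give_identity_with_zero_rmse():
    pts = np.array([(10.0, 10.0), (50.0, 12.0), (30.0, 40.0)])
    tf = beadreg.estimate_similarity(pts, pts)
    assert tf.rotation_deg == pytest.approx(0.0, abs=1e-9)
    assert tf.scale == pytest.approx(1.0, abs=1e-12)
    assert tf.rmse_px == pytest.approx(0.0, abs=1e-9)


def test_known_transform_recovered():
    rng = np.random.default_rng(2)
    ref = rng.uniform(0, 200, (8, 2))
    truth = SimilarityTransform(rotation_deg=5.0, scale=0.98, dx=30.0, dy=-12.0)
    mov = truth.apply(ref) + rng.normal(0, 0.1, (8, 2))
    tf = beadreg.estimate_similarity(ref, mov)
    assert tf.rotation_deg == pytest.approx(5.0, abs=0.1)
    assert tf.scale == pytest.approx(0.98, abs=0.002)
    assert tf.dx == pytest.approx(30.0, abs=0.5)
    assert tf.dy == pytest.approx(-12.0, abs=0.5)


def test_estimate_matches_brute_force_grid_search():
    rng = np.random.default_rng(3)
    ref = rng.uniform(0, 100, (10, 2))
    truth = SimilarityTransform(rotation_deg=3.35, scale=1.017, dx=5.0, dy=-2.0)
    mov = truth.apply(ref) + rng.normal(0, 0.3, (10, 2))
    _, rot_bf, scale_bf, _ = brute_force_similarity(ref, mov)
    tf = beadreg.estimate_similarity(ref, mov)
    assert tf.rotation_deg == pytest.approx(rot_bf, abs=0.05)
    assert tf.scale == pytest.approx(scale_bf, abs=0.001)


def test_degenerate_cloud_rejected():
    pts = np.array([(5.0, 5.0), (5.0, 5.0)])
    with pytest.raises(ValueError):
        beadreg.estimate_similarity(pts, pts)


def test_no_reflection_in_fit():
    rng = np.random.default_rng(5)
    ref = rng.uniform(0, 100, (6, 2))
    mov = SimilarityTransform(rotation_deg=20.0, scale=1.05, dx=2.0, dy=1.0).apply(ref)
    tf = beadreg.estimate_similarity(ref, mov)
    assert np.linalg.det(tf.matrix[:2, :2]) > 0
    # even a mirrored correspondence is fitted with a proper rotation
    # (poorly, but without ever introducing a reflection)
    mirrored = mov.copy()
    mirrored[:, 0] *= -1
    tf2 = beadreg.estimate_similarity(ref, mirrored)
    assert np.linalg.det(tf2.matrix[:2, :2]) > 0
    assert tf2.rmse_px > 1.0  # and the residual exposes the mismatch


# ------------------------------------------------------------------ recovery suite


def test_fifty_random_transforms_recovered_from_noisy_beads():
    """Parameter recovery within 0.2 deg / 0.005 scale / 1 px from >= 4 beads
    carrying 0.5 px centroid noise, across the plausible transform range."""
    rng = np.random.default_rng(1234)
    worst = {"rot": 0.0, "scale": 0.0, "shift": 0.0}
    for _ in range(50):
        n = int(rng.integers(4, 9))
        ref = rng.uniform(0, 600, (n, 2))
        truth = SimilarityTransform(
            rotation_deg=float(rng.uniform(-30, 30)),
            scale=float(rng.uniform(0.9, 1.1)),
            dx=float(rng.uniform(-40, 40)),
            dy=float(rng.uniform(-40, 40)),
        )
        mov = truth.apply(ref) + rng.normal(0, 0.5, (n, 2))
        perm = rng.permutation(n)
        pairs = beadreg.match_beads(_bead_set(ref), _bead_set(mov[perm]))
        assert len(pairs) >= 4
        tf = beadreg.estimate_similarity(
            ref[[i for i, _ in pairs]], mov[perm][[j for _, j in pairs]]
        )
        worst["rot"] = max(worst["rot"], abs(tf.rotation_deg - truth.rotation_deg))
        worst["scale"] = max(worst["scale"], abs(tf.scale - truth.scale))
        # shift accuracy = displacement error where the beads actually are
        center = ref.mean(axis=0, keepdims=True)
        shift_err = float(np.linalg.norm(tf.apply(center) - truth.apply(center)))
        worst["shift"] = max(worst["shift"], shift_err)
    assert worst["rot"] <= 0.2
    assert worst["scale"] <= 0.005
    assert worst["shift"] <= 1.0


def test_recovery_error_shrinks_with_more_beads():
    """Transform recovery improves (in expectation) as fiducials are added."""
    rng = np.random.default_rng(99)
    truth = SimilarityTransform(rotation_deg=8.0, scale=1.03, dx=10.0, dy=-4.0)

    def mean_err(n_beads: int) -> float:
        errs = []
        for _ in range(40):
            ref = rng.uniform(0, 400, (n_beads, 2))
            mov = truth.apply(ref) + rng.normal(0, 0.5, (n_beads, 2))
            tf = beadreg.estimate_similarity(ref, mov)
            errs.append(abs(tf.rotation_deg - truth.rotation_deg))
        return float(np.mean(errs))

    assert mean_err(12) < mean_err(4)


# ------------------------------------------------------------------ warping


def test_warp_identity_unchanged(femur_phantom):
    _, _, stack, _ = femur_phantom
    out, valid = beadreg.warp_to_reference(stack, SimilarityTransform(), ("trap",))
    assert np.array_equal(out["trap"].pixels, stack["trap"].pixels)
    assert valid.all()


def test_warp_round_trip_and_fiducial_residual(noiseless_femur_phantom):
    spec, _, stack, truth = noiseless_femur_phantom
    T = SimilarityTransform.about_center(4.0, 0.97, (12, -6), spec.image_shape)
    moved, truth2 = ph.misregister(stack, truth, T)
    registered, tf = beadreg.register_stack(moved)
    # recovered transform close to the applied one
    assert tf.rotation_deg == pytest.approx(T.rotation_deg, abs=0.1)
    assert tf.scale == pytest.approx(T.scale, abs=0.002)
    # mean absolute error away from borders below 2 % of dynamic range
    interior = np.s_[40:-40, 40:-40]
    orig = stack["trap"].pixels[interior]
    back = registered["trap"].pixels[interior]
    assert np.abs(orig - back).mean() < 0.02 * np.ptp(orig)
    # beads in the registered channel land within 1 px of reference beads
    ref_beads = beadreg.detect_beads(stack["label1"], 6.0)
    back_beads = beadreg.detect_beads(registered["trap"], 6.0)
    assert len(back_beads) >= 3
    for c in back_beads.centroids:
        d = np.linalg.norm(ref_beads.centroids - c, axis=1).min()
        assert d <= 1.0
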