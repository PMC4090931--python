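import numpy as np
import pytest

from bonemorph.segmentation import BinaryMask
from bonemorph.projection import (
    classify_surface,
    interlabel_thickness,
    project_signal,
    surface_normals,
)


def flat_scene(px=1.0, n=80, bone_row=50):
    bone = np.zeros((n, n), dtype=bool)
    bone[bone_row:] = True
    return BinaryMask(bone, px, "mineral")


def band(shape, rows, cols, px=1.0, role="label1"):
    m = np.zeros(shape, dtype=bool)
    m[rows[0] : rows[1], cols[0] : cols[1]] = True
    return BinaryMask(m, px, role)


def ray_march_oracle(signal, bone, drow, dcol, max_steps=200):
    """Per-pixel brute force: march every signal pixel along (drow, dcol) one
    pixel at a time, recording the first step at which it overlaps bone."""
    travels = {}
    nr, nc = bone.shape
    for r, c in zip(*np.nonzero(signal)):
        for t in range(max_steps + 1):
            rr = int(round(r + t * drow))
            cc = int(round(c + t * dcol))
            if 0 <= rr < nr and 0 <= cc < nc and bone[rr, cc]:
                travels[(r, c)] = t
                break
    return travels


# ------------------------------------------------------------------ normals


def test_flat_top_normals_are_exact():
    bone = flat_scene()
    surface, normals = surface_normals(bone)
    top = surface.pixels[:, 0] == 50
    away_from_sides = (surface.pixels[:, 1] > 5) & (surface.pixels[:, 1] < 74)
    v = normals.vectors[top & away_from_sides]
    assert np.allclose(v, [0.0, -1.0])


def test_circle_normals_radial_within_3_degrees():
    n = 140
    yy, xx = np.mgrid[0:n, 0:n]
    bone = BinaryMask((xx - 70) ** 2 + (yy - 70) ** 2 <= 50**2, 1.0)
    surface, normals = surface_normals(bone)
    radial = surface.pixels[:, ::-1].astype(float) - 70.0  # (x, y) outward
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    dots = np.clip(np.sum(normals.vectors * radial, axis=1), -1, 1)
    assert np.rad2deg(np.arccos(dots)).max() <= 3.0


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        surface_normals(BinaryMask(np.zeros((10, 10), dtype=bool), 1.0))


# ------------------------------------------------------------------ projection


def test_band_touching_surface_has_zero_leading_edge():
    bone = flat_scene()
    sig = band((80, 80), (48, 51), (20, 60))  # overlaps the surface row
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=50.0)
    comp = [c for c in proj.components if not c["discarded"]][0]
    assert comp["leading_edge_px"] == 0
    hit_cols = surface.pixels[proj.surface_pixels_hit][:, 1]
    assert set(range(20, 60)) <= set(hit_cols.tolist())


def test_leading_edge_distance_exact():
    bone = flat_scene()
    sig = band((80, 80), (36, 40), (20, 60))  # leading pixel row 39, bone at 50
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=50.0)
    comp = [c for c in proj.components if not c["discarded"]][0]
    assert comp["leading_edge_px"] == 11


def test_midpoint_is_leading_plus_half_extent():
    bone = flat_scene()
    sig = band((80, 80), (36, 40), (20, 60))  # thickness 4 px, leading 11
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=50.0)
    comp = [c for c in proj.components if not c["discarded"]][0]
    assert comp["midpoint_px"] == pytest.approx(11 + 4 / 2.0)


def test_matches_ray_march_oracle_on_flat_surface():
    bone = flat_scene()
    sig = band((80, 80), (30, 37), (25, 55))
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=60.0)
    oracle = ray_march_oracle(sig.pixels, bone.pixels, 1.0, 0.0)
    comp = [c for c in proj.components if not c["discarded"]][0]
    assert comp["leading_edge_px"] == min(oracle.values())
    assert comp["lagging_edge_px"] == max(oracle.values())
    # per-surface-pixel leading distances equal the oracle's column minima
    lead = proj.surf_leading_px
    for idx in proj.surface_pixels_hit:
        r, c = surface.pixels[idx]
        col_travels = [t for (rr, cc), t in oracle.items() if cc == c]
        assert lead[idx] == min(col_travels)


def test_matches_ray_march_oracle_on_circle():
    n = 160
    yy, xx = np.mgrid[0:n, 0:n]
    bone = BinaryMask((xx - 80) ** 2 + (yy - 80) ** 2 <= 45**2, 1.0)
    # arc-shaped signal above the circle
    sig_mask = ((xx - 80) ** 2 + (yy - 80) ** 2 <= 58**2) & (
        (xx - 80) ** 2 + (yy - 80) ** 2 >= 53**2
    ) & (np.abs(xx - 80) <= 10) & (yy < 80)
    sig = BinaryMask(sig_mask, 1.0, "label1")
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=60.0)
    comp = [c for c in proj.components if not c["discarded"]][0]
    dcol, drow = comp["direction"]
    oracle = ray_march_oracle(sig.pixels, bone.pixels, drow, dcol)
    assert comp["leading_edge_px"] == min(oracle.values())


def test_component_beyond_max_travel_discarded():
    bone = flat_scene()
    sig = band((80, 80), (2, 6), (20, 60))  # 44 px above the bone
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=20.0)
    assert all(c["discarded"] for c in proj.components)
    assert len(proj.surface_pixels_hit) == 0


def test_no_bone_rejected():
    empty = BinaryMask(np.zeros((40, 40), dtype=bool), 1.0)
    sig = band((40, 40), (5, 8), (5, 30))
    with pytest.raises(ValueError, match="no bone"):
        project_signal(sig, empty, *surface_normals(flat_scene(n=40, bone_row=30)))


# ------------------------------------------------------------------ interlabel


def _project_two_labels(l1_rows, l2_rows, cols=(20, 60), px=1.0):
    bone = flat_scene(px=px)
    surface, normals = surface_normals(bone)
    p1 = project_signal(band((80, 80), l1_rows, cols, px, "label1"), bone, surface, normals, 100.0)
    p2 = project_signal(band((80, 80), l2_rows, cols, px, "label2"), bone, surface, normals, 100.0)
    return p1, p2


def test_interlabel_thickness_from_leading_edges():
    # L1 leading edge 15 px out, L2 leading edge 5 px out, 1 um pixels
    p1, p2 = _project_two_labels((31, 35), (41, 45))
    ir = interlabel_thickness(p1, p2, 1.0, mode="leading")
    assert ir.mean_um == pytest.approx(10.0)
    assert np.all(ir.values_um == 10.0)


def test_midpoint_mode_matches_for_equal_thickness_bands():
    p1, p2 = _project_two_labels((31, 35), (41, 45))
    ir = interlabel_thickness(p1, p2, 1.0, mode="midpoint")
    assert ir.mean_um == pytest.approx(10.0)


def test_coincident_labels_give_zero():
    p1, p2 = _project_two_labels((41, 45), (41, 45))
    ir = interlabel_thickness(p1, p2, 1.0)
    assert ir.mean_um == pytest.approx(0.0)


def test_inverted_label_order_excluded_and_counted():
    p1, p2 = _project_two_labels((41, 45), (31, 35))  # L1 closer than L2
    ir = interlabel_thickness(p1, p2, 1.0)
    assert ir.mean_um is None
    assert ir.n_negative_excluded > 0


def test_no_double_label_gives_absent_result():
    p1, p2 = _project_two_labels((31, 35), (41, 45), cols=(20, 30))
    p2b = _project_two_labels((31, 35), (41, 45), cols=(50, 60))[1]
    ir = interlabel_thickness(p1, p2b, 1.0)
    assert ir.mean_um is None
    assert ir.n_pixels == 0


def test_interlabel_invariant_under_90_degree_rotation():
    bone = flat_scene()
    l1 = band((80, 80), (31, 35), (20, 60), role="label1")
    l2 = band((80, 80), (41, 45), (20, 60), role="label2")

    def measure(b, m1, m2):
        surface, normals = surface_normals(b)
        p1 = project_signal(m1, b, surface, normals, 100.0)
        p2 = project_signal(m2, b, surface, normals, 100.0)
        return interlabel_thickness(p1, p2, 1.0).mean_um

    base = measure(bone, l1, l2)
    rot = lambda m: BinaryMask(np.rot90(m.pixels), m.pixel_size_um, m.channel_role)
    assert measure(rot(bone), rot(l1), rot(l2)) == pytest.approx(base)


# ------------------------------------------------------------------ classification


def test_no_signals_means_all_unlabeled():
    bone = flat_scene()
    surface, _ = surface_normals(bone)
    cls = classify_surface(surface, {}, 25.6, 1.0)
    assert cls.unlabeled.all()
    assert not cls.l1.any() and not cls.trap.any()


def test_trap_beyond_proximity_excluded_from_surface():
    # TRAP component 30 um from the surface with a 25.6 um rule: it projects,
    # but is not surface-associated
    bone = flat_scene()
    sig = band((80, 80), (17, 21), (30, 50), role="trap")  # leading edge 29 px
    surface, normals = surface_normals(bone)
    proj = project_signal(sig, bone, surface, normals, max_travel_um=76.8)
    assert len(proj.surface_pixels_hit) > 0  # it did reach the surface
    cls = classify_surface(surface, {"trap": proj}, 25.6, 1.0)
    assert not cls.trap.any()
    near = band((80, 80), (40, 44), (30, 50), role="trap")  # leading edge 6 px
    proj2 = project_signal(near, bone, surface, normals, max_travel_um=76.8)
    cls2 = classify_surface(surface, {"trap": proj2}, 25.6, 1.0)
    assert cls2.trap.any()


def test_exclusive_classes_partition_surface():
    p1, p2 = _project_two_labels((31, 35), (41, 45), cols=(20, 45))
    surface = p1.surface
    cls = classify_surface(surface, {"label1": p1, "label2": p2}, 25.6, 1.0)
    total = cls.sl1.sum() + cls.sl2.sum() + cls.dl.sum() + cls.unlabeled.sum()
    assert total == len(surface)
    assert np.array_equal(cls.l2, cls.sl2 | cls.dl)
    assert np.array_equal(cls.l1, cls.sl1 | cls.dl)


def test_ap_equal_to_l2_makes_ap_only_empty():
    bone = flat_scene()
    surface, normals = surface_normals(bone)
    m = band((80, 80), (41, 45), (20, 60))
    proj = project_signal(m, bone, surface, normals, 100.0)
    cls = classify_surface(
        surface, {"ap": proj, "label2": proj}, 25.6, 1.0
    )
    assert np.array_equal(cls.ap_l2, cls.ap)
    assert not cls.ap_only.any()
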