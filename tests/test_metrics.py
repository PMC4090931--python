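import numpy as np
import pytest

from bonemorph.metrics import (
    cellular_metrics,
    compare_groups,
    dynamic_from_fractions,
    dynamic_metrics,
    static_metrics,
)
from bonemorph.projection import classify_surface, surface_normals
from bonemorph.report import HistomorphometryReport
from bonemorph.segmentation import BinaryMask
from bonemorph.surface_roi import ROIMask

from conftest import stripe_bone


def full_roi(shape, px, site="femur"):
    return ROIMask(np.ones(shape, dtype=bool), site, np.prod(shape) * (px / 1000.0) ** 2, 50.0, px)


# ------------------------------------------------------------------ static


def test_roi_entirely_bone_gives_100_percent():
    bone = BinaryMask(np.ones((50, 50), dtype=bool), 2.0)
    out = static_metrics(bone, full_roi((50, 50), 2.0))
    assert out["bv_tv"] == 100.0


def test_periodic_stripes_match_closed_form():
    # bone width 40 um, gap 160 um at 2 um/px: BV/TV 20 %, Tb.Th 40 um,
    # Tb.N 5 /mm, Tb.Sp 160 um
    bone = stripe_bone(n=400, width=20, gap=80, pixel_size_um=2.0)
    roi = full_roi((400, 400), 2.0)
    # restrict the ROI to whole periods so the area ratio is exact
    roi.pixels[:] = False
    roi.pixels[40 : 40 + 300] = True  # 3 whole periods of 100 px
    out = static_metrics(bone, roi)
    assert out["bv_tv"] == pytest.approx(20.0)
    assert out["tb_th"] == pytest.approx(40.0, abs=2.0)
    assert out["tb_n"] == pytest.approx(5.0, abs=0.3)
    assert out["tb_sp"] == pytest.approx(160.0, abs=4.0)


def test_no_bone_yields_zero_bvtv_and_absent_derived():
    bone = BinaryMask(np.zeros((50, 50), dtype=bool), 2.0)
    out = static_metrics(bone, full_roi((50, 50), 2.0))
    assert out["bv_tv"] == 0.0
    assert out["tb_th"] is None and out["tb_n"] is None and out["tb_sp"] is None


def test_empty_roi_rejected():
    bone = BinaryMask(np.ones((50, 50), dtype=bool), 2.0)
    roi = full_roi((50, 50), 2.0)
    roi.pixels[:] = False
    with pytest.raises(ValueError):
        static_metrics(bone, roi)


# ------------------------------------------------------------------ dynamic


def test_labeled_surface_identities_from_printed_fractions():
    # single 41.24 %, double 13.32 % -> any-labeled 54.56 %, mineralizing 33.94 %
    out = dynamic_from_fractions(sls_bs=41.24, dls_bs=13.32)
    assert round(out["ls_bs"], 2) == 54.56
    assert round(out["ms_bs"], 2) == 33.94


def test_bfr_from_mar_and_mineralizing_surface():
    out = dynamic_from_fractions(sls_bs=41.24, dls_bs=13.32, mar=2.31)
    assert round(out["bfr"], 2) == 0.78


def test_mar_from_interlabel_thickness_and_interval():
    out = dynamic_from_fractions(sls_bs=0.0, dls_bs=0.0, ir_l_th=15.36, label_interval_days=7.0)
    assert round(out["mar"], 2) == 2.19


def test_mar_scales_inversely_with_interval():
    a = dynamic_from_fractions(10.0, 5.0, ir_l_th=12.0, label_interval_days=4.0)
    b = dynamic_from_fractions(10.0, 5.0, ir_l_th=12.0, label_interval_days=8.0)
    assert a["mar"] == 2 * b["mar"]


def test_no_labels_yields_absent_ratios_not_zero():
    out = dynamic_from_fractions(sls_bs=0.0, dls_bs=0.0)
    assert out["ls_bs"] == 0.0 and out["ms_bs"] == 0.0
    assert out["sls_ls"] is None and out["dls_sls"] is None
    assert out["mar"] is None and out["bfr"] is None


def test_dynamic_metrics_counts_only_roi_surface():
    from bonemorph.projection import project_signal

    bone = BinaryMask(np.zeros((60, 60), dtype=bool), 1.0)
    bone.pixels[30:40, 10:50] = True
    surface, normals = surface_normals(bone)
    sig = BinaryMask(np.zeros((60, 60), dtype=bool), 1.0, "label1")
    sig.pixels[25:28, 10:30] = True
    proj = project_signal(sig, bone, surface, normals, 50.0)
    cls = classify_surface(surface, {"label1": proj}, 25.6, 1.0)
    out_all = dynamic_metrics(cls, None, 5.0)
    sel = surface.pixels[:, 1] < 30  # only the labeled half
    out_roi = dynamic_metrics(cls, None, 5.0, within=sel)
    assert out_roi["l1_bs"] > out_all["l1_bs"]


# ------------------------------------------------------------------ cellular


def _flat_cls(trap_rows=None, px=1.0):
    bone = BinaryMask(np.zeros((80, 80), dtype=bool), px)
    bone.pixels[50:] = True
    surface, normals = surface_normals(bone)
    projs = {}
    trap_mask = BinaryMask(np.zeros((80, 80), dtype=bool), px, "trap")
    if trap_rows:
        from bonemorph.projection import project_signal

        trap_mask.pixels[trap_rows[0] : trap_rows[1], 20:40] = True
        projs["trap"] = project_signal(trap_mask, bone, surface, normals, 76.8)
    cls = classify_surface(surface, projs, 25.6, px)
    return bone, surface, cls, trap_mask


def test_no_trap_gives_zero_tv_and_absent_on_ratio():
    bone, surface, cls, trap = _flat_cls()
    out = cellular_metrics(cls, trap, full_roi((80, 80), 1.0), 25.6)
    assert out["trap_tv"] == 0.0
    assert out["trap_on_trap"] is None


def test_trap_on_trap_counts_proximal_fraction():
    # one band adjacent to the surface, plus far-away activity appended
    bone, surface, cls, trap = _flat_cls(trap_rows=(46, 50))
    trap.pixels[5:9, 20:40] = True  # 45 px away: within ROI, not near surface
    out = cellular_metrics(cls, trap, full_roi((80, 80), 1.0), 25.6)
    assert out["trap_on_trap"] == pytest.approx(50.0)
    assert out["trap_tv"] == pytest.approx(100.0 * 160 / 6400)


def test_ap_flags_equal_l2_degenerate_identity():
    bone = BinaryMask(np.zeros((80, 80), dtype=bool), 1.0)
    bone.pixels[50:] = True
    surface, normals = surface_normals(bone)
    from bonemorph.projection import project_signal

    sig = BinaryMask(np.zeros((80, 80), dtype=bool), 1.0)
    sig.pixels[46:49, 10:70] = True
    proj = project_signal(sig, bone, surface, normals, 76.8)
    cls = classify_surface(surface, {"ap": proj, "label2": proj}, 25.6, 1.0)
    out = cellular_metrics(cls, None, full_roi((80, 80), 1.0), 25.6)
    assert out["ap_l2_bs"] == out["ap_bs"] > 0
    assert out["ap_only_bs"] == 0.0


# ------------------------------------------------------------------ group stats


def _reports(values):
    return [HistomorphometryReport(bv_tv=v) for v in values]


def test_identical_groups_give_t0_p1():
    a = _reports([10.0, 12.0, 14.0])
    df = compare_groups(a, _reports([10.0, 12.0, 14.0]))
    row = df.loc["bv_tv"]
    assert row["t"] == 0.0 and row["p"] == 1.0


def test_constant_nonzero_differences_flagged_degenerate():
    df = compare_groups(_reports([1.0, 2.0, 3.0, 4.0]), _reports([2.0, 3.0, 4.0, 5.0]))
    row = df.loc["bv_tv"]
    assert row["p"] is None
    assert "degenerate" in row["flag"]


def test_paired_t_matches_textbook_computation():
    rng = np.random.default_rng(0)
    x = rng.normal(10, 2, 12)
    y = x + rng.normal(0.5, 1, 12)
    df = compare_groups(_reports(x), _reports(y))
    row = df.loc["bv_tv"]
    d = x - y
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy.stats import t as tdist

    p_ref = 2 * tdist.sf(abs(t_ref), len(d) - 1)
    assert row["t"] == pytest.approx(t_ref, abs=1e-10)
    assert row["p"] == pytest.approx(p_ref, abs=1e-10)
    assert row["n_pairs"] == 12


def test_pairwise_deletion_of_absent_values():
    a = _reports([1.0, 2.0, 3.0])
    b = _reports([1.5, None, 3.5])
    df = compare_groups(a, b)
    assert df.loc["bv_tv", "n_pairs"] == 2


def test_unequal_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups(_reports([1.0]), _reports([1.0, 2.0]))
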