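"""Static, dynamic and cellular histomorphometric measurements.

Measured ("M") quantities come straight from masks and surface
classifications; calculated ("C") quantities derive from them:

* ``LS/BS = sLS/BS + dLS/BS`` — any-labeled surface
* ``MS/BS = dLS/BS + sLS/BS / 2`` — mineralizing surface (Parfitt convention:
  double-labeled surface counts fully, single-labeled half)
* ``MAR = Ir.L.Th / label interval`` (µm/day)
* ``BFR = MAR x MS/BS`` (fraction form, µm³/µm²/day)
* plate model: ``Tb.N = (BV/TV) / Tb.Th`` and ``Tb.Sp = 1/Tb.N - Tb.Th``

Ratios with zero denominators are *absent* (None), never 0: a section with
no labeled surface has no MAR, which is different from a MAR of 0.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import morphology

from .projection import InterlabelResult, SurfaceClassification
from .report import HistomorphometryReport
from .segmentation import BinaryMask
from .surface_roi import ROIMask

__all__ = [
    "static_metrics",
    "dynamic_metrics",
    "dynamic_from_fractions",
    "cellular_metrics",
    "compare_groups",
    "DEFAULT_LABEL_INTERVAL_DAYS",
]

log = logging.getLogger(__name__)

#: days between the two label injections (calcein day -7, alizarin day -2)
DEFAULT_LABEL_INTERVAL_DAYS = 5.0


def _pct(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def static_metrics(bone: BinaryMask, roi: ROIMask) -> dict[str, Optional[float]]:
    """BV/TV, Tb.Th (medial-axis measured), Tb.N and Tb.Sp (plate model)."""
    if not roi.pixels.any():
        raise ValueError("empty ROI")
    px = bone.pixel_size_um
    in_roi = bone.pixels & roi.pixels
    tv = float(roi.pixels.sum())
    bv = float(in_roi.sum())
    bv_tv = 100.0 * bv / tv
    if bv == 0:
        return {"bv_tv": 0.0, "tb_th": None, "tb_n": None, "tb_sp": None}
    skel, dist = morphology.medial_axis(in_roi, return_distance=True)
    if not skel.any():
        return {"bv_tv": bv_tv, "tb_th": None, "tb_n": None, "tb_sp": None}
    tb_th = 2.0 * float(dist[skel].mean()) * px
    tb_n_per_mm = (bv_tv / 100.0) / tb_th * 1000.0
    tb_sp = 1000.0 / tb_n_per_mm - tb_th
    return {"bv_tv": bv_tv, "tb_th": tb_th, "tb_n": tb_n_per_mm, "tb_sp": tb_sp}


def dynamic_from_fractions(
    sls_bs: Optional[float],
    dls_bs: Optional[float],
    l1_bs: Optional[float] = None,
    l2_bs: Optional[float] = None,
    ir_l_th: Optional[float] = None,
    label_interval_days: Optional[float] = None,
    mar: Optional[float] = None,
) -> dict[str, Optional[float]]:
    """Derive the calculated dynamic quantities from measured fractions.

    All surface fractions are percentages.  Either ``ir_l_th`` (with the
    label interval) or ``mar`` may seed the rate chain; BFR uses MS/BS in
    fraction form.
    """
    out: dict[str, Optional[float]] = {
        "sls_bs": sls_bs,
        "dls_bs": dls_bs,
        "l1_bs": l1_bs,
        "l2_bs": l2_bs,
        "ir_l_th": ir_l_th,
        "ls_bs": None,
        "ms_bs": None,
        "sls_ls": None,
        "dls_ls": None,
        "dls_sls": None,
        "l1_only_bs": None,
        "l2_only_bs": None,
        "mar": mar,
        "bfr": None,
    }
    if sls_bs is not None and dls_bs is not None:
        out["ls_bs"] = sls_bs + dls_bs
        out["ms_bs"] = dls_bs + sls_bs / 2.0
        ls = out["ls_bs"]
        if ls and ls > 0:
            out["sls_ls"] = 100.0 * sls_bs / ls
            out["dls_ls"] = 100.0 * dls_bs / ls
        if sls_bs > 0:
            out["dls_sls"] = 100.0 * dls_bs / sls_bs
        if l1_bs is not None:
            out["l1_only_bs"] = l1_bs - dls_bs
        if l2_bs is not None:
            out["l2_only_bs"] = l2_bs - dls_bs
    if mar is None and ir_l_th is not None and label_interval_days:
        out["mar"] = ir_l_th / label_interval_days
    if out["mar"] is not None and out["ms_bs"] is not None:
        out["bfr"] = out["mar"] * out["ms_bs"] / 100.0
    return out


def dynamic_metrics(
    cls: SurfaceClassification,
    ir: Optional[InterlabelResult],
    label_interval_days: float = DEFAULT_LABEL_INTERVAL_DAYS,
    within: Optional[np.ndarray] = None,
) -> dict[str, Optional[float]]:
    """All dynamic fields from a surface classification and the inter-label
    thickness; ``within`` restricts to the surface pixels inside the ROI."""
    sel = np.ones(len(cls.surface), dtype=bool) if within is None else within
    bs = float(sel.sum())
    if bs == 0:
        raise ValueError("zero bone surface")
    f = lambda flags: 100.0 * float((flags & sel).sum()) / bs
    ir_um = ir.mean_um if ir is not None else None
    return dynamic_from_fractions(
        sls_bs=f(cls.sl1) + f(cls.sl2),
        dls_bs=f(cls.dl),
        l1_bs=f(cls.l1),
        l2_bs=f(cls.l2),
        ir_l_th=ir_um,
        label_interval_days=label_interval_days,
    )


def cellular_metrics(
    cls: SurfaceClassification,
    trap_mask: Optional[BinaryMask],
    roi: ROIMask,
    proximity_um: float,
    within: Optional[np.ndarray] = None,
) -> dict[str, Optional[float]]:
    """Osteoblast (AP) and osteoclast (TRAP) activity measurements.

    Surface fractions come from the classification; TRAP/TV is total TRAP
    area inside the ROI and TRAP_on/TRAP the proportion of it within
    ``proximity_um`` of the bone surface.
    """
    if not roi.pixels.any():
        raise ValueError("empty ROI")
    sel = np.ones(len(cls.surface), dtype=bool) if within is None else within
    bs = float(sel.sum())
    f = lambda flags: _pct(float((flags & sel).sum()), bs)
    out: dict[str, Optional[float]] = {
        "ap_bs": f(cls.ap),
        "ap_l2_bs": f(cls.ap_l2),
        "ap_only_bs": f(cls.ap_only),
        "trap_bs": f(cls.trap),
        "trap_l2_bs": f(cls.trap_l2),
        "trap_only_bs": f(cls.trap_only),
        "trap_tv": None,
        "trap_on_trap": None,
    }
    if trap_mask is not None:
        if trap_mask.shape != roi.pixels.shape:
            raise ValueError("TRAP mask and ROI must share geometry")
        trap_in = trap_mask.pixels & roi.pixels
        out["trap_tv"] = _pct(float(trap_in.sum()), float(roi.pixels.sum()))
        n_trap = float(trap_in.sum())
        if n_trap > 0:
            surface_map = cls.surface.index >= 0
            dist_px = ndimage.distance_transform_edt(~surface_map)
            prox = proximity_um / trap_mask.pixel_size_um
            n_on = float((trap_in & (dist_px <= prox)).sum())
            out["trap_on_trap"] = 100.0 * n_on / n_trap
    return out


def compare_groups(
    a: Sequence[HistomorphometryReport], b: Sequence[HistomorphometryReport]
) -> pd.DataFrame:
    """Paired t test per measurement between two matched groups of sections.

    Pairs with an absent value on either side are dropped (pairwise
    deletion); degenerate cases (constant nonzero differences, < 2 complete
    pairs) report an absent p value and are flagged.
    """
    if len(a) != len(b):
        raise ValueError("groups must be paired (equal length)")
    if len(a) < 2:
        raise ValueError("need at least 2 paired sections")
    rows = []
    names = a[0].measurements().keys()
    for name in names:
        xs, ys = [], []
        for ra, rb in zip(a, b):
            va, vb = getattr(ra, name), getattr(rb, name)
            if va is not None and vb is not None:
                xs.append(va)
                ys.append(vb)
        n = len(xs)
        row: dict = {
            "measurement": name,
            "n_pairs": n,
            "mean_a": np.mean(xs) if n else None,
            "sd_a": np.std(xs, ddof=1) if n >= 2 else None,
            "mean_b": np.mean(ys) if n else None,
            "sd_b": np.std(ys, ddof=1) if n >= 2 else None,
            "t": None,
            "p": None,
            "flag": "",
        }
        if n >= 2:
            diffs = np.asarray(xs) - np.asarray(ys)
            if np.allclose(diffs, 0.0):
                row["t"], row["p"] = 0.0, 1.0
            elif np.std(diffs, ddof=1) == 0:
                row["flag"] = "degenerate: constant nonzero differences"
            else:
                t, p = stats.ttest_rel(xs, ys)
                row["t"], row["p"] = float(t), float(p)
        else:
            row["flag"] = "fewer than 2 complete pairs"
        rows.append(row)
    return pd.DataFrame(rows).set_index("measurement")
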