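"""Synthetic bone-section phantoms with exact, closed-form ground truth.

The phantom stands in for scanned non-decalcified cryosections: it renders the
six fluorescence channels (mineral, two mineralization labels, TRAP, AP, DAPI)
of simple trabecular geometry — axis-aligned stripes and circular annuli — so
that every downstream quantity (surface fractions, inter-label thickness,
registration transform, tile offsets) is known analytically from the spec
rather than re-measured from the rendered raster.

Geometry conventions (inherited by every module): 0-based pixel coordinates,
row-major, row index increasing downward; points as (x, y) = (col, row).

Mineralization labels are modeled as bands in the marrow whose *leading edge*
(the edge nearest the bone) sits at a configurable offset from the bone
surface; the first-injected label (L1, calcein, day -7) lies farther out than
the second (L2, alizarin complexone, day -2), so the true inter-label
thickness is simply ``label1_offset_um - label2_offset_um``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .image_io import ChannelStack, RasterImage, build_stack
from .transforms import SimilarityTransform

__all__ = [
    "Stripe",
    "Annulus",
    "CellSite",
    "PhantomSpec",
    "PhantomTruth",
    "TileGrid",
    "make_trabecular_phantom",
    "split_into_tiles",
    "apply_similarity",
    "add_shading",
    "misregister",
    "femur_spec",
    "annulus_spec",
]

#: default rendered intensities, 16-bit-friendly 0-1000 scale.  The source
#: acquisition fixes exposure manually and reports no intensity statistics,
#: so these are free working values chosen to give three well separated
#: populations (outside background / marrow background / signal).
DEFAULT_INTENSITY = {
    "background": 30.0,
    "marrow": 110.0,
    "bone": 600.0,
    "label": 800.0,
    "cell": 700.0,
    "bead": 1000.0,
    "dapi": 500.0,
}


@dataclass(frozen=True)
class Stripe:
    """Axis-aligned bar of bone.

    ``start_um`` is the top row (horizontal) or left column (vertical) of the
    bar; ``span_um`` bounds its extent along the perpendicular axis.  Only
    ``labeled`` horizontal stripes carry mineralization labels and cell sites
    and enter the surface-fraction ground truth (they model trabeculae inside
    the ROI; unlabeled stripes model cortex / growth plate).
    """

    start_um: float
    width_um: float
    span_um: tuple[float, float]
    axis: str = "horizontal"  # "horizontal" | "vertical"
    labeled: bool = False

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"stripe axis must be horizontal|vertical, got {self.axis!r}")
        if self.width_um <= 0 or self.span_um[1] <= self.span_um[0]:
            raise ValueError("stripe width and span must be positive")
        if self.labeled and self.axis != "horizontal":
            raise ValueError("only horizontal stripes can be labeled")


@dataclass(frozen=True)
class Annulus:
    """Circular cortical shell, optionally with gaps (chipped cortex)."""

    center_um: tuple[float, float]  # (x, y)
    outer_radius_um: float
    thickness_um: float
    #: (center angle deg, gap arc length um) wedges removed from the ring
    gaps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.thickness_um <= 0 or self.outer_radius_um <= self.thickness_um:
            raise ValueError("annulus needs 0 < thickness < outer radius")


@dataclass(frozen=True)
class CellSite:
    """One TRAP or AP blob anchored to a labeled stripe's surface.

    ``anchor`` is the fractional position along the stripe span; ``surface``
    selects the top or bottom face.  ``off_surface`` places the blob beyond
    the osteoclast/osteoblast proximity window so that it contributes to
    TRAP/TV but not to any surface fraction.
    """

    stripe_index: int
    anchor: float
    surface: str = "top"  # "top" | "bottom"
    on_label2: bool = False
    off_surface: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.anchor <= 1.0:
            raise ValueError("anchor must be in [0, 1]")
        if self.surface not in ("top", "bottom"):
            raise ValueError("surface must be top|bottom")


@dataclass(frozen=True)
class PhantomSpec:
    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    trabecula_geometry: tuple = ()
    label1_offset_um: float = 16.0
    label2_offset_um: float = 6.0
    label_band_width_um: float = 6.0
    labeled_fraction_l1: float = 0.5
    labeled_fraction_l2: float = 0.4
    #: fractional start of each label band along the stripe span; together
    #: with the labeled fractions this controls single/double/unlabeled mix
    label1_start_fraction: float = 0.0
    label2_start_fraction: float = 0.3
    trap_sites: tuple[CellSite, ...] = ()
    ap_sites: tuple[CellSite, ...] = ()
    cell_diameter_um: float = 12.0
    off_surface_distance_um: float = 40.0
    bead_centers_um: tuple[tuple[float, float], ...] = ()
    bead_diameter_um: float = 6.0
    noise_sd: float = 5.0
    seed: int = 0
    site: str = "femur"
    intensity: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY))

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("labeled_fraction_l1", "labeled_fraction_l2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.label1_offset_um < 0 or self.label2_offset_um < 0:
            raise ValueError("label offsets must be >= 0")
        if self.label_band_width_um <= 0:
            raise ValueError("label band width must be > 0")

    def px(self, um: float) -> int:
        return int(round(um / self.pixel_size_um))


@dataclass
class PhantomTruth:
    """Everything the pipeline is supposed to recover, known exactly."""

    bone_mask: np.ndarray
    surface_pixels: np.ndarray  # (N, 2) rows, cols of measured (labeled-stripe) surface
    fractions: dict[str, Optional[float]]  # Table-style "M" quantities, percent
    true_interlabel_um: float
    true_transform: SimilarityTransform = field(default_factory=SimilarityTransform)
    tile_offsets: Optional[np.ndarray] = None  # (rows, cols, 2) placements
    bead_centers_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    growth_plate_row: Optional[int] = None
    interior_mask: Optional[np.ndarray] = None

    def validate(self) -> None:
        excl = [
            self.fractions.get(k) or 0.0
            for k in ("sls_bs", "dls_bs")
        ]
        if any(not (0.0 <= (v or 0.0) <= 100.0) for v in self.fractions.values() if v is not None):
            raise ValueError("truth fractions must lie in [0, 100] %")
        if sum(excl) > 100.0 + 1e-9:
            raise ValueError("exclusive surface fractions exceed 100 %")

    def to_json(self) -> str:
        d = {
            "fractions": self.fractions,
            "true_interlabel_um": self.true_interlabel_um,
            "true_transform": json.loads(self.true_transform.to_json()),
            "bead_centers_px": self.bead_centers_px.tolist(),
            "growth_plate_row": self.growth_plate_row,
        }
        return json.dumps(d, indent=2)


# --------------------------------------------------------------------------- rendering


def _stripe_px(spec: PhantomSpec, s: Stripe) -> tuple[int, int, int, int]:
    """(r0, r1, c0, c1) half-open pixel bounds of a stripe."""
    a0, a1 = spec.px(s.start_um), spec.px(s.start_um + s.width_um)
    b0, b1 = spec.px(s.span_um[0]), spec.px(s.span_um[1])
    if s.axis == "horizontal":
        return a0, a1, b0, b1
    return b0, b1, a0, a1


def _check_bounds(spec: PhantomSpec, name: str, r0: int, r1: int, c0: int, c1: int) -> None:
    nr, nc = spec.image_shape
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc or r1 - r0 < 2 or c1 - c0 < 2:
        raise ValueError(
            f"phantom primitive {name} out of bounds: rows [{r0},{r1}), cols [{c0},{c1}) "
            f"for image {spec.image_shape}"
        )


def _render_annulus(spec: PhantomSpec, a: Annulus, bone: np.ndarray) -> None:
    nr, nc = spec.image_shape
    cx = a.center_um[0] / spec.pixel_size_um
    cy = a.center_um[1] / spec.pixel_size_um
    r_out = a.outer_radius_um / spec.pixel_size_um
    r_in = (a.outer_radius_um - a.thickness_um) / spec.pixel_size_um
    if cy - r_out < -0.5 or cx - r_out < -0.5 or cy + r_out > nr - 0.5 or cx + r_out > nc - 0.5:
        raise ValueError(f"phantom primitive {a} out of bounds for image {spec.image_shape}")
    yy, xx = np.mgrid[0:nr, 0:nc]
    dist = np.hypot(xx - cx, yy - cy)
    ring = (dist <= r_out) & (dist >= r_in)
    ang = np.rad2deg(np.arctan2(yy - cy, xx - cx))
    r_mid_um = a.outer_radius_um - a.thickness_um / 2.0
    for center_deg, arc_um in a.gaps:
        half_deg = math.degrees(arc_um / (2.0 * r_mid_um)) if r_mid_um > 0 else 0.0
        diff = (ang - center_deg + 180.0) % 360.0 - 180.0
        ring &= ~(np.abs(diff) <= half_deg)
    bone |= ring


def _disk(center_rc: tuple[int, int], radius_px: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2


def _disk_col_span(radius_px: float) -> int:
    """Number of pixel columns a rasterized integer-centered disk spans."""
    return 2 * int(math.floor(radius_px)) + 1


def make_trabecular_phantom(spec: PhantomSpec) -> tuple[ChannelStack, PhantomTruth]:
    """Render all channels of a synthetic section and its analytic truth.

    The returned truth fractions are computed from the spec's integer pixel
    arithmetic (band pixel counts over stripe perimeters), never by measuring
    the rendered raster.
    """
    nr, nc = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    px = spec.px

    bone = np.zeros((nr, nc), dtype=bool)
    l1 = np.zeros((nr, nc), dtype=float)
    l2 = np.zeros((nr, nc), dtype=float)
    trap = np.zeros((nr, nc), dtype=float)
    ap = np.zeros((nr, nc), dtype=float)

    inten = {**DEFAULT_INTENSITY, **spec.intensity}

    labeled_stripes: list[tuple[int, int, int, int]] = []
    for prim in spec.trabecula_geometry:
        if isinstance(prim, Stripe):
            r0, r1, c0, c1 = _stripe_px(spec, prim)
            _check_bounds(spec, repr(prim), r0, r1, c0, c1)
            bone[r0:r1, c0:c1] = True
            if prim.labeled:
                labeled_stripes.append((r0, r1, c0, c1))
        elif isinstance(prim, Annulus):
            _render_annulus(spec, prim, bone)
        else:
            raise TypeError(f"unknown phantom primitive {prim!r}")

    # ---------------- mineralization label bands + analytic surface bookkeeping
    bw = max(1, px(spec.label_band_width_um))
    o1, o2 = px(spec.label1_offset_um), px(spec.label2_offset_um)
    bs_total = 0
    n_l1 = n_l2 = n_dl = 0
    for r0, r1, c0, c1 in labeled_stripes:
        h, length = r1 - r0, c1 - c0
        bs_total += 2 * length + 2 * h - 4
        s1 = int(round(spec.label1_start_fraction * length))
        e1 = min(length, s1 + int(round(spec.labeled_fraction_l1 * length)))
        s2 = int(round(spec.label2_start_fraction * length))
        e2 = min(length, s2 + int(round(spec.labeled_fraction_l2 * length)))
        n1, n2 = e1 - s1, e2 - s2
        ndl = max(0, min(e1, e2) - max(s1, s2))
        n_l1 += 2 * n1
        n_l2 += 2 * n2
        n_dl += 2 * ndl
        for band, off, seg in ((l1, o1, (s1, e1)), (l2, o2, (s2, e2))):
            if seg[1] <= seg[0]:
                continue
            cols = (c0 + seg[0], c0 + seg[1])
            # leading-edge convention: a band pixel at row r above the stripe
            # first overlaps bone after (r0 - r) one-pixel moves, so the band's
            # nearest row sits exactly `off` pixels of travel from the surface.
            top = (r0 - off - bw + 1, r0 - off + 1)
            bot = (r1 - 1 + off, r1 - 1 + off + bw)
            for rr0, rr1 in (top, bot):
                if rr0 < 0 or rr1 > nr:
                    raise ValueError(
                        f"label band rows [{rr0},{rr1}) out of bounds for stripe "
                        f"rows [{r0},{r1})"
                    )
                other_bone = bone[rr0:rr1, cols[0] : cols[1]].copy()
                pr0, pr1 = max(rr0, r0), min(rr1, r1)  # parent stripe overlap is fine
                if pr1 > pr0:
                    other_bone[pr0 - rr0 : pr1 - rr0, :] = False
                if other_bone.any():
                    raise ValueError(
                        f"label band rows [{rr0},{rr1}) intersects another bone "
                        "primitive; increase stripe spacing"
                    )
                band[rr0:rr1, cols[0] : cols[1]] = inten["label"]

    # ---------------- TRAP / AP cell blobs
    cell_r = spec.cell_diameter_um / 2.0 / spec.pixel_size_um
    span_px = _disk_col_span(cell_r)
    off_px = px(spec.off_surface_distance_um)
    cell_counts = {"trap": {"l2": 0, "only": 0, "on": 0, "total": 0}, "ap": {"l2": 0, "only": 0, "on": 0, "total": 0}}
    for role, sites, channel in (("trap", spec.trap_sites, trap), ("ap", spec.ap_sites, ap)):
        for site in sites:
            if site.stripe_index >= len(labeled_stripes):
                raise ValueError(f"cell site {site} references missing labeled stripe")
            r0, r1, c0, c1 = labeled_stripes[site.stripe_index]
            if site.off_surface:
                # beyond the stripe's end face, level with its center: far
                # from every surface, yet inside the analysis region
                cr = (r0 + r1) // 2
                cc = c1 - 1 + off_px + int(math.floor(cell_r)) + 1
            else:
                cc = c0 + int(round(site.anchor * (c1 - c0 - 1)))
                cc = min(max(cc, c0 + span_px // 2), c1 - 1 - span_px // 2)
                if site.surface == "top":
                    cr = r0 - 2 - int(math.floor(cell_r)) - 1
                else:
                    cr = r1 - 1 + 2 + int(math.floor(cell_r)) + 1
            disk = _disk((cr, cc), cell_r, (nr, nc))
            if bone[disk].any():
                raise ValueError(f"cell site {site} overlaps bone")
            channel[disk] = inten["cell"]
            cell_counts[role]["total"] += 1
            if not site.off_surface:
                cell_counts[role]["on"] += 1
                if site.on_label2:
                    cell_counts[role]["l2"] += span_px
                else:
                    cell_counts[role]["only"] += span_px

    # ---------------- fiducial beads: green+red beads share the label channels,
    # and reappear on the TRAP / AP scans where they anchor the registration
    bead_r = spec.bead_diameter_um / 2.0 / spec.pixel_size_um
    bead_centers_px = []
    for bx, by in spec.bead_centers_um:
        cr, cc = int(round(by / spec.pixel_size_um)), int(round(bx / spec.pixel_size_um))
        if not (0 <= cr < nr and 0 <= cc < nc):
            raise ValueError(f"bead center ({bx}, {by}) um out of bounds")
        disk = _disk((cr, cc), bead_r, (nr, nc))
        for channel in (l1, l2, trap, ap):
            channel[disk] = inten["bead"]
        bead_centers_px.append((cc, cr))

    # ---------------- backgrounds and noise
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(bone) if bone.any() else np.zeros_like(bone)
    marrow = hull & ~bone

    mineral = np.full((nr, nc), inten["background"], dtype=float)
    mineral[bone] = inten["bone"]

    dapi = np.full((nr, nc), inten["background"], dtype=float)
    n_nuclei = int(marrow.sum() * 0.002)
    if n_nuclei:
        rows, cols = np.nonzero(marrow)
        pick = rng.choice(len(rows), size=n_nuclei, replace=False)
        for i in pick:
            dapi[_disk((rows[i], cols[i]), 2.5, (nr, nc))] = inten["dapi"]

    def cell_channel(signal: np.ndarray) -> np.ndarray:
        out = np.full((nr, nc), inten["background"], dtype=float)
        out[hull] = inten["marrow"]
        np.copyto(out, signal, where=signal > 0)
        return out

    def label_channel(signal: np.ndarray) -> np.ndarray:
        out = np.full((nr, nc), inten["background"], dtype=float)
        np.copyto(out, signal, where=signal > 0)
        return out

    channels = {
        "mineral": mineral,
        "label1": label_channel(l1),
        "label2": label_channel(l2),
        "trap": cell_channel(trap),
        "ap": cell_channel(ap),
        "dapi": dapi,
    }
    if spec.noise_sd > 0:
        for role in channels:
            noisy = channels[role] + rng.normal(0.0, spec.noise_sd, size=(nr, nc))
            channels[role] = np.clip(noisy, 0.0, None)

    stack = build_stack(
        {role: RasterImage(arr, spec.pixel_size_um) for role, arr in channels.items()},
        site=spec.site,
    )

    # ---------------- analytic truth fractions (percent of measured surface)
    def frac(n: float) -> Optional[float]:
        return None if bs_total == 0 else 100.0 * n / bs_total

    fractions: dict[str, Optional[float]]
    if bs_total:
        sls = n_l1 + n_l2 - 2 * n_dl
        dls = n_dl
        ls = sls + dls
        fractions = {
            "l1_bs": frac(n_l1),
            "l2_bs": frac(n_l2),
            "l1_only_bs": frac(n_l1 - n_dl),
            "l2_only_bs": frac(n_l2 - n_dl),
            "sls_bs": frac(sls),
            "dls_bs": frac(dls),
            "ls_bs": frac(ls),
            "ms_bs": frac(dls + sls / 2.0),
            "trap_bs": frac(cell_counts["trap"]["l2"] + cell_counts["trap"]["only"]),
            "trap_l2_bs": frac(cell_counts["trap"]["l2"]),
            "trap_only_bs": frac(cell_counts["trap"]["only"]),
            "ap_bs": frac(cell_counts["ap"]["l2"] + cell_counts["ap"]["only"]),
            "ap_l2_bs": frac(cell_counts["ap"]["l2"]),
            "ap_only_bs": frac(cell_counts["ap"]["only"]),
        }
        tot = cell_counts["trap"]["total"]
        fractions["trap_on_trap"] = 100.0 * cell_counts["trap"]["on"] / tot if tot else None
    else:
        fractions = {}

    # measured surface = boundary pixels of labeled stripes
    surf = []
    for r0, r1, c0, c1 in labeled_stripes:
        for c in range(c0, c1):
            surf.append((r0, c))
            surf.append((r1 - 1, c))
        for r in range(r0 + 1, r1 - 1):
            surf.append((r, c0))
            surf.append((r, c1 - 1))
    surface_pixels = np.array(surf, dtype=int) if surf else np.empty((0, 2), dtype=int)

    truth = PhantomTruth(
        bone_mask=bone,
        surface_pixels=surface_pixels,
        fractions=fractions,
        true_interlabel_um=(o1 - o2) * spec.pixel_size_um,
        bead_centers_px=np.array(bead_centers_px, dtype=float).reshape(-1, 2),
    )
    truth.validate()
    return stack, truth


# --------------------------------------------------------------------------- canned geometries


def femur_spec(
    image_shape: tuple[int, int] = (700, 700),
    pixel_size_um: float = 2.0,
    n_trabeculae: int = 3,
    trabecula_width_um: float = 40.0,
    cortex_um: float = 60.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    with_cells: bool = True,
    with_beads: bool = True,
) -> tuple[PhantomSpec, int]:
    """A distal-femur-like phantom: growth plate, two cortices, trabeculae.

    Returns (spec, growth_plate_row).  The interior marrow cavity is the
    rectangle between the cortices below the growth plate.
    """
    nr, nc = image_shape
    h_um = nr * pixel_size_um
    w_um = nc * pixel_size_um
    # wide margin ring: fiducial beads live here and must stay in-field
    # under the plausible slide misplacements (a few degrees, a few px)
    margin = 100.0
    gp_top = margin
    geom: list = [
        # growth plate spanning between the cortices
        Stripe(start_um=gp_top, width_um=cortex_um, span_um=(margin, w_um - margin)),
        # left / right cortices
        Stripe(start_um=margin, width_um=cortex_um, span_um=(gp_top, h_um - margin), axis="vertical"),
        Stripe(start_um=w_um - margin - cortex_um, width_um=cortex_um, span_um=(gp_top, h_um - margin), axis="vertical"),
        # bottom cortex
        Stripe(start_um=h_um - margin - cortex_um, width_um=cortex_um, span_um=(margin, w_um - margin)),
    ]
    interior_top = gp_top + cortex_um
    interior_bot = h_um - margin - cortex_um
    trab_span = (margin + cortex_um + 360.0, w_um - margin - cortex_um - 360.0)
    start0 = interior_top + 500.0
    pitch = (interior_bot - 250.0 - start0) / max(n_trabeculae, 1)
    for i in range(n_trabeculae):
        geom.append(
            Stripe(
                start_um=start0 + i * pitch,
                width_um=trabecula_width_um,
                span_um=trab_span,
                labeled=True,
            )
        )
    trap_sites: tuple[CellSite, ...] = ()
    ap_sites: tuple[CellSite, ...] = ()
    if with_cells and n_trabeculae >= 2:
        # anchors sit in the L2-only window (on_label2) or the unlabeled
        # window of the default label layout (L1 0-0.5, L2 0.3-0.7)
        trap_sites = (
            CellSite(0, 0.60, "top", on_label2=True),
            CellSite(0, 0.85, "bottom"),
            CellSite(1, 0.45, "bottom", off_surface=True),
            CellSite(1, 0.62, "top", on_label2=True),
        )
        ap_sites = (
            CellSite(0, 0.64, "top", on_label2=True),
            CellSite(1, 0.80, "bottom"),
            CellSite(min(2, n_trabeculae - 1), 0.75, "bottom"),
        )
    beads: tuple[tuple[float, float], ...] = ()
    if with_beads:
        beads = (
            (margin / 2, margin / 2),
            (w_um - margin / 2, margin / 2 + 10),
            (margin / 2 + 6, h_um - margin / 2),
            (w_um - margin / 2 - 8, h_um - margin / 2 - 4),
            (w_um / 2, margin / 2 - 20),
        )
    spec = PhantomSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        trabecula_geometry=tuple(geom),
        trap_sites=trap_sites,
        ap_sites=ap_sites,
        bead_centers_um=beads,
        noise_sd=noise_sd,
        seed=seed,
        site="femur",
    )
    growth_plate_row = spec.px(gp_top + cortex_um)
    return spec, growth_plate_row


def femur_interior_mask(spec: PhantomSpec) -> np.ndarray:
    """True marrow-cavity rectangle of a femur_spec phantom."""
    strips = [p for p in spec.trabecula_geometry if isinstance(p, Stripe) and not p.labeled]
    horiz = sorted((s for s in strips if s.axis == "horizontal"), key=lambda s: s.start_um)
    vert = sorted((s for s in strips if s.axis == "vertical"), key=lambda s: s.start_um)
    top = spec.px(horiz[0].start_um + horiz[0].width_um)
    bot = spec.px(horiz[-1].start_um)
    left = spec.px(vert[0].start_um + vert[0].width_um)
    right = spec.px(vert[-1].start_um)
    mask = np.zeros(spec.image_shape, dtype=bool)
    mask[top:bot, left:right] = True
    return mask


def annulus_spec(
    image_shape: tuple[int, int] = (520, 520),
    pixel_size_um: float = 4.0,
    outer_radius_um: float = 950.0,
    thickness_um: float = 80.0,
    gaps: tuple[tuple[float, float], ...] = (),
    noise_sd: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A vertebral-body-like phantom: one circular cortical shell."""
    nr, nc = image_shape
    center = (nc * pixel_size_um / 2.0, nr * pixel_size_um / 2.0)
    ann = Annulus(center_um=center, outer_radius_um=outer_radius_um, thickness_um=thickness_um, gaps=gaps)
    return PhantomSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        trabecula_geometry=(ann,),
        trap_sites=(),
        ap_sites=(),
        bead_centers_um=(),
        noise_sd=noise_sd,
        seed=seed,
        site="vertebra",
    )


# --------------------------------------------------------------------------- tiles


@dataclass
class TileGrid:
    """Grid of overlapping fractional scans of one whole-section image."""

    tiles: list[list[RasterImage]]
    nominal_overlap: float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        shapes = {t.shape for row in self.tiles for t in row}
        if len(shapes) != 1:
            raise ValueError(f"all tiles must share one shape, got {shapes}")
        self.tile_shape = next(iter(shapes))


def split_into_tiles(
    image: RasterImage, tile_shape: tuple[int, int], overlap_fraction: float
) -> tuple[TileGrid, np.ndarray]:
    """Cut a whole image into an overlapping tile grid, returning truth offsets.

    Adjacent fractional scans share a nominal 10-15 % overlap; the last tile
    of each row/column is clamped to the image edge so tiles jointly cover
    the image and reassembly at the returned offsets is lossless.
    """
    if not 0.05 <= overlap_fraction <= 0.5:
        raise ValueError(f"overlap_fraction must be in [0.05, 0.5], got {overlap_fraction}")
    th, tw = tile_shape
    nr, nc = image.shape
    if th >= nr or tw >= nc:
        raise ValueError(f"tile shape {tile_shape} must be smaller than image {image.shape}")

    def starts(total: int, tile: int) -> list[int]:
        step = max(1, int(round(tile * (1.0 - overlap_fraction))))
        n = max(2, int(np.ceil((total - tile) / step)) + 1)
        # distribute evenly so every adjacent pair shares (about) the same
        # overlap instead of clamping the last tile to the edge
        return [int(round(i * (total - tile) / (n - 1))) for i in range(n)]

    rows = starts(nr, th)
    cols = starts(nc, tw)
    tiles: list[list[RasterImage]] = []
    offsets = np.zeros((len(rows), len(cols), 2), dtype=int)
    for i, r in enumerate(rows):
        row_tiles = []
        for j, c in enumerate(cols):
            row_tiles.append(image.with_pixels(image.pixels[r : r + th, c : c + tw].copy()))
            offsets[i, j] = (r, c)
        tiles.append(row_tiles)
    grid = TileGrid(tiles=tiles, nominal_overlap=overlap_fraction, grid_shape=(len(rows), len(cols)))
    return grid, offsets


# --------------------------------------------------------------------------- misregistration & shading


def apply_similarity(
    stack: ChannelStack,
    transform: SimilarityTransform,
    channels: Sequence[str] = ("trap", "ap"),
) -> ChannelStack:
    """Resample the listed channels (with their beads) under ``transform``.

    Models the TRAP/AP slide being restained and replaced on the stage:
    |rotation| <= 30 deg, scale within [0.9, 1.1] (tape shrinkage).
    The identity transform returns the input channels bit-exactly.
    """
    if transform.scale <= 0:
        raise ValueError("scale must be > 0")
    if abs(transform.rotation_deg) > 30.0:
        raise ValueError(f"|rotation| must be <= 30 deg, got {transform.rotation_deg}")
    if not 0.9 <= transform.scale <= 1.1:
        raise ValueError(f"scale must be in [0.9, 1.1], got {transform.scale}")
    from skimage.transform import warp

    new = {}
    for role in channels:
        img = stack[role]
        if transform.is_identity():
            new[role] = img.with_pixels(img.pixels.copy())
            continue
        # output(T(x)) = input(x)  =>  inverse_map = T^{-1}
        warped = warp(
            img.astype_float(),
            inverse_map=transform.inverse().to_skimage(),
            order=1,
            mode="constant",
            cval=float(np.median(img.pixels)),
            preserve_range=True,
        )
        new[role] = img.with_pixels(warped)
    return stack.replace(**new)


def misregister(
    stack: ChannelStack,
    truth: PhantomTruth,
    transform: SimilarityTransform,
    channels: Sequence[str] = ("trap", "ap"),
) -> tuple[ChannelStack, PhantomTruth]:
    """Apply a similarity to the cell channels and record it in the truth."""
    moved = apply_similarity(stack, transform, channels)
    truth2 = dataclasses.replace(truth, true_transform=transform)
    return moved, truth2


def add_shading(
    image: RasterImage, ramp: tuple[float, float], offset: float = 0.0, max_value: float = 65535.0
) -> RasterImage:
    """Add a planar illumination gradient: out = in + gx*col + gy*row + offset.

    Values are clipped into [0, max_value]; clipping is reported via a log
    message rather than an error, mirroring camera saturation.
    """
    gx, gy = ramp
    nr, nc = image.shape
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    out = image.astype_float() + gx * cols + gy * rows + offset
    n_clip = int(np.sum((out < 0) | (out > max_value)))
    if n_clip:
        import logging

        logging.getLogger(__name__).warning(
            "add_shading clipped %d pixels to [0, %g]", n_clip, max_value
        )
    return image.with_pixels(np.clip(out, 0.0, max_value))


def write_phantom(directory: str | Path, stack: ChannelStack, truth: PhantomTruth) -> None:
    """Write the phantom channels as TIFFs plus the truth JSON alongside."""
    directory = Path(directory)
    stack.write(directory)
    (directory / "truth.json").write_text(truth.to_json())
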