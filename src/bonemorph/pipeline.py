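"""End-to-end orchestration: channels in, histomorphometry report out.

Stage order mirrors the acquisition workflow: (tile assembly) -> bead
registration of the TRAP/AP scans -> shade correction -> per-channel
segmentation -> surface smoothing / cortex repair -> ROI selection ->
surface-normal projection -> measurement.  Every stage's parameters,
timing and QC overlay are written next to the report so a run can be
audited stage by stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import beadreg, metrics, projection, surface_roi
from .config import RunConfig
from .image_io import ChannelStack, RasterImage, read_channel, build_stack, write_report
from .phantom import TileGrid
from .preprocess import ShadeParams, shade_correct
from .report import HistomorphometryReport
from .segmentation import BinaryMask, DEFAULT_STEPS, iterative_otsu
from .transforms import SimilarityTransform

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

#: a label/cell mask covering more than this fraction of the image is a
#: thresholding artifact of a signal-free channel, not signal
MAX_PLAUSIBLE_SIGNAL_FRACTION = 0.25


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _load_stack(config: RunConfig) -> ChannelStack:
    from .assembly import assemble_tiles

    images = {}
    for role, path in config.channels.items():
        p = Path(path)
        if p.is_dir():
            if config.tile_grid is None:
                raise PipelineError("assemble", f"channel {role} is a tile directory but no tile_grid set")
            nrows, ncols = config.tile_grid
            tiles = [
                [read_channel(p / f"r{i}c{j}.tiff", config.pixel_size_um) for j in range(ncols)]
                for i in range(nrows)
            ]
            grid = TileGrid(tiles=tiles, nominal_overlap=config.tile_overlap, grid_shape=(nrows, ncols))
            images[role], _ = assemble_tiles(grid, config.k)
        else:
            images[role] = read_channel(p, config.pixel_size_um)
    # tile-assembled channels can come out slightly different sizes; crop to common
    if images:
        h = min(img.shape[0] for img in images.values())
        w = min(img.shape[1] for img in images.values())
        images = {r: RasterImage(img.pixels[:h, :w], img.pixel_size_um) for r, img in images.items()}
    return build_stack(images, config.site)


def _segment(
    stack: ChannelStack, role: str, config: RunConfig
) -> Optional[BinaryMask]:
    img = stack[role]
    if config.shade.enabled and role in config.shade.channels:
        img = shade_correct(img, ShadeParams(window_um=config.shade.window_um))
    steps = config.segmentation_steps.get(role, DEFAULT_STEPS.get(role, 1))
    mask = iterative_otsu(img, steps=steps, channel_role=role)
    if role != "mineral":
        frac = mask.pixels.mean()
        if frac > MAX_PLAUSIBLE_SIGNAL_FRACTION:
            log.warning(
                "channel %s: mask covers %.0f%% of the image; treating as signal-free",
                role,
                100 * frac,
            )
            return None
    return mask


def run_pipeline(
    config: RunConfig, stack: Optional[ChannelStack] = None
) -> HistomorphometryReport:
    """Execute every stage and write report + QC artifacts to config.out_dir.

    ``stack`` may be supplied directly (e.g. a phantom) instead of reading
    the configured channel paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    run_log: dict = {"config": config.resolved(), "stages": timings, "notes": []}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)

    def fail(stage: str, exc: Exception) -> PipelineError:
        run_log["failed_stage"] = stage
        run_log["error"] = str(exc)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
        return PipelineError(stage, str(exc))

    # ------------------------------------------------------------ load / assemble
    try:
        if stack is None:
            stack = _load_stack(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise fail("load", exc) from exc
    tick("load")

    # ------------------------------------------------------------ registration
    transform = SimilarityTransform()
    try:
        if config.register and ("trap" in stack or "ap" in stack) and "label1" in stack:
            stack, transform = beadreg.register_stack(
                stack, config.bead_diameter_um, tuple(r for r in ("trap", "ap") if r in stack)
            )
            (out / "transform.json").write_text(transform.to_json())
    except beadreg.InsufficientFiducialsError as exc:
        run_log["notes"].append(f"registration skipped: {exc}")
        log.warning("registration skipped: %s", exc)
    except Exception as exc:
        raise fail("register", exc) from exc
    tick("register")

    # ------------------------------------------------------------ segmentation
    masks: dict[str, Optional[BinaryMask]] = {}
    try:
        for role in ("mineral", "label1", "label2", "trap", "ap", "gfp"):
            if role in stack:
                masks[role] = _segment(stack, role, config)
        bone_raw = masks["mineral"]
        assert bone_raw is not None
    except Exception as exc:
        raise fail("segment", exc) from exc
    tick("segment")

    # ------------------------------------------------------------ surface & ROI
    try:
        geom = surface_roi.smooth_surface(
            bone_raw, config.roi.smooth_despeckle_um, config.roi.smooth_close_um
        )
        geom = surface_roi.repair_cortex(geom, config.roi.max_gap_um)
        if config.site == "femur":
            roi = surface_roi.select_femur_roi(
                geom,
                growth_plate_row=int(config.roi.growth_plate_row),  # type: ignore[arg-type]
                inset_um=config.roi.inset_um,
                start_um=config.roi.start_um,
                target_area_mm2=config.roi.target_area_mm2,
                tile_um=config.roi.tile_um,
            )
        else:
            roi = surface_roi.select_vertebra_roi(
                geom,
                band_um=config.roi.band_um,
                mode=config.roi.vertebra_mode,
                tile_um=config.roi.tile_um,
            )
        if not roi.pixels.any():
            raise ValueError("ROI selection produced an empty region")
    except Exception as exc:
        raise fail("roi", exc) from exc
    tick("roi")

    # ------------------------------------------------------------ projection
    try:
        surface, normals = projection.surface_normals(geom)
        in_roi = roi.pixels[surface.pixels[:, 0], surface.pixels[:, 1]]
        projs: dict[str, projection.ProjectedSignal] = {}
        cell_travel = projection.CELL_MAX_TRAVEL_FACTOR * config.proximity_um
        for role, travel in (
            ("label1", config.label_max_travel_um),
            ("label2", config.label_max_travel_um),
            ("gfp", config.label_max_travel_um),
            ("trap", cell_travel),
            ("ap", cell_travel),
        ):
            m = masks.get(role)
            if m is not None and m.pixels.any():
                projs[role] = projection.project_signal(m, geom, surface, normals, travel)
        cls = projection.classify_surface(
            surface, projs, config.proximity_um, config.pixel_size_um
        )
        ir = None
        if "label1" in projs and "label2" in projs:
            ir = projection.interlabel_thickness(
                projs["label1"],
                projs["label2"],
                config.pixel_size_um,
                mode=config.interlabel_mode,
                within=in_roi,
            )
    except Exception as exc:
        raise fail("project", exc) from exc
    tick("project")

    # ------------------------------------------------------------ measurement
    try:
        report = HistomorphometryReport(
            provenance={
                "pixel_size_um": config.pixel_size_um,
                "site": config.site,
                "label_interval_days": config.label_interval_days,
                "proximity_um": config.proximity_um,
                "roi_area_mm2": roi.area_mm2,
                "registration": json.loads(transform.to_json()),
                "config": config.resolved(),
            }
        )
        report.update(metrics.static_metrics(bone_raw, roi))
        if in_roi.any():
            report.update(
                metrics.dynamic_metrics(cls, ir, config.label_interval_days, within=in_roi)
            )
            report.update(
                metrics.cellular_metrics(
                    cls, masks.get("trap"), roi, config.proximity_um, within=in_roi
                )
            )
        write_report(report, out / "report.json", "json")
        write_report(report, out / "report.csv", "csv")
    except Exception as exc:
        raise fail("measure", exc) from exc
    tick("measure")

    # ------------------------------------------------------------ QC artifacts
    try:
        _write_qc(out, stack, masks, roi, surface, cls, in_roi)
    except Exception as exc:  # QC failures must not void the measurements
        run_log["notes"].append(f"qc overlay failed: {exc}")
        log.warning("qc overlay failed: %s", exc)
    tick("qc")

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return report


def _write_qc(
    out: Path,
    stack: ChannelStack,
    masks: dict[str, Optional[BinaryMask]],
    roi,
    surface,
    cls,
    in_roi: np.ndarray,
) -> None:
    """Color-coded overlays mirroring the audit views of the workflow."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mineral = stack["mineral"].astype_float()
    base = mineral / (mineral.max() or 1.0)

    fig, axes = plt.subplots(1, 3, figsize=(15, 5))
    axes[0].imshow(base, cmap="gray")
    axes[0].contour(roi.pixels, colors="yellow", linewidths=0.5)
    axes[0].set_title("mineral + ROI")
    bone = masks["mineral"]
    overlay = np.zeros(base.shape + (3,))
    overlay[..., 0] = base
    if bone is not None:
        overlay[..., 1] = np.where(bone.pixels, 0.8, 0.0)
    axes[1].imshow(overlay)
    axes[1].set_title("thresholded bone")
    axes[2].imshow(base, cmap="gray")
    colors = {"l1": "lime", "l2": "red", "ap": "orange", "trap": "cyan"}
    any_class = False
    for attr, color in colors.items():
        flags = getattr(cls, attr) & in_roi
        pts = surface.pixels[flags]
        if len(pts):
            axes[2].scatter(pts[:, 1], pts[:, 0], s=0.3, c=color, label=attr)
            any_class = True
    if any_class:
        axes[2].legend(markerscale=20, fontsize=7)
    axes[2].set_title("projected surface classes")
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out / "qc_overlay.png", dpi=110)
    plt.close(fig)
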