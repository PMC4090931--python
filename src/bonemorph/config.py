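"""Run configuration: one YAML document drives the whole pipeline.

Every physical parameter is explicit — pixel size, channel file mapping,
bone site, ROI geometry, the label injection interval — with documented
defaults for the algorithmic knobs (k = 0.3 for stitching, 25.6 µm cell
proximity, 250 µm femur inset, 50 µm ROI tiles, 2.1 mm² femur target area,
770 µm vertebral band).  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .image_io import CHANNEL_ROLES
from .projection import MOUSE_PROXIMITY_UM

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RoiConfig:
    growth_plate_row: Optional[int] = None
    inset_um: float = 250.0
    start_um: float = 400.0
    target_area_mm2: float = 2.1
    band_um: float = 770.0
    vertebra_mode: str = "central"
    tile_um: float = 50.0
    max_gap_um: float = 150.0
    smooth_despeckle_um: float = 10.0
    smooth_close_um: float = 10.0


@dataclass
class ShadeConfig:
    enabled: bool = False
    window_um: float = 600.0
    channels: tuple[str, ...] = ("mineral", "label1", "label2", "trap", "ap")


@dataclass
class RunConfig:
    pixel_size_um: float
    site: str
    channels: dict[str, str] = field(default_factory=dict)
    k: float = 0.3
    tile_grid: Optional[tuple[int, int]] = None
    tile_overlap: float = 0.15
    register: bool = True
    bead_diameter_um: float = 6.0
    shade: ShadeConfig = field(default_factory=ShadeConfig)
    segmentation_steps: dict[str, int] = field(default_factory=dict)
    roi: RoiConfig = field(default_factory=RoiConfig)
    proximity_um: float = MOUSE_PROXIMITY_UM
    label_interval_days: float = 5.0
    label_max_travel_um: float = 50.0
    interlabel_mode: str = "leading"
    seed: int = 0
    out_dir: str = "bonemorph_out"

    def resolved(self) -> dict[str, Any]:
        """Plain-dict snapshot of every effective parameter (for the log)."""
        import dataclasses

        return dataclasses.asdict(self)


_REQUIRED = ("pixel_size_um", "site")

_TOP_KEYS = {
    "pixel_size_um",
    "site",
    "channels",
    "k",
    "tile_grid",
    "tile_overlap",
    "register",
    "bead_diameter_um",
    "shade",
    "segmentation_steps",
    "roi",
    "proximity_um",
    "label_interval_days",
    "label_max_travel_um",
    "interlabel_mode",
    "seed",
    "out_dir",
}


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ConfigError(f"{name} = {value} outside allowed range [{lo}, {hi}]")


def validate_config(source: str | dict[str, Any] | Path) -> RunConfig:
    """Parse and validate a run configuration (YAML text, path, or dict)."""
    if isinstance(source, Path):
        raw = yaml.safe_load(source.read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")

    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required keys: {', '.join(missing)}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    site = raw["site"]
    if site not in ("femur", "vertebra"):
        raise ConfigError(f"site must be femur|vertebra, got {site!r}")

    channels = dict(raw.get("channels", {}))
    for role in channels:
        if role not in CHANNEL_ROLES:
            raise ConfigError(f"unknown channel role {role!r} in channels")

    roi_raw = dict(raw.get("roi", {}))
    roi_known = set(RoiConfig.__dataclass_fields__)
    bad = set(roi_raw) - roi_known
    if bad:
        raise ConfigError(f"unknown roi keys: {sorted(bad)}")
    roi = RoiConfig(**roi_raw)

    shade_raw = dict(raw.get("shade", {}))
    bad = set(shade_raw) - set(ShadeConfig.__dataclass_fields__)
    if bad:
        raise ConfigError(f"unknown shade keys: {sorted(bad)}")
    if "channels" in shade_raw:
        shade_raw["channels"] = tuple(shade_raw["channels"])
    shade = ShadeConfig(**shade_raw)

    steps = {str(k): int(v) for k, v in dict(raw.get("segmentation_steps", {})).items()}
    for role, n in steps.items():
        if role not in CHANNEL_ROLES:
            raise ConfigError(f"segmentation_steps: unknown role {role!r}")
        if n not in (1, 2, 3):
            raise ConfigError(f"segmentation_steps[{role}] must be 1..3, got {n}")

    cfg = RunConfig(
        pixel_size_um=float(raw["pixel_size_um"]),
        site=site,
        channels=channels,
        k=float(raw.get("k", 0.3)),
        tile_grid=tuple(raw["tile_grid"]) if raw.get("tile_grid") else None,
        tile_overlap=float(raw.get("tile_overlap", 0.15)),
        register=bool(raw.get("register", True)),
        bead_diameter_um=float(raw.get("bead_diameter_um", 6.0)),
        shade=shade,
        segmentation_steps=steps,
        roi=roi,
        proximity_um=float(raw.get("proximity_um", MOUSE_PROXIMITY_UM)),
        label_interval_days=float(raw.get("label_interval_days", 5.0)),
        label_max_travel_um=float(raw.get("label_max_travel_um", 50.0)),
        interlabel_mode=str(raw.get("interlabel_mode", "leading")),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "bonemorph_out")),
    )

    if cfg.pixel_size_um <= 0:
        raise ConfigError(f"pixel_size_um must be > 0, got {cfg.pixel_size_um}")
    _check_range("k", cfg.k, 0.0, 1.0)
    _check_range("tile_overlap", cfg.tile_overlap, 0.05, 0.5)
    if cfg.proximity_um <= 0 or cfg.label_interval_days <= 0:
        raise ConfigError("proximity_um and label_interval_days must be > 0")
    if cfg.interlabel_mode not in ("leading", "midpoint"):
        raise ConfigError("interlabel_mode must be leading|midpoint")
    if cfg.site == "femur" and cfg.roi.growth_plate_row is None:
        raise ConfigError("femur analysis requires roi.growth_plate_row")
    if cfg.roi.vertebra_mode not in ("central", "band"):
        raise ConfigError("roi.vertebra_mode must be central|band")
    return cfg
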