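"""Reading, validating and writing channel images and measurement reports.

Each fluorescence channel (mineral, mineralization labels, TRAP, AP, DAPI,
optional GFP) lives in its own grayscale file — one file per microscope
filter.  Pixel size in µm/px is mandatory user input and is never guessed
from file metadata: every physical threshold downstream (25.6 µm proximity,
400 µm ROI offset, ...) depends on it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import imageio.v3 as iio
import tifffile

from .report import HistomorphometryReport

__all__ = [
    "CHANNEL_ROLES",
    "RasterImage",
    "ChannelStack",
    "read_channel",
    "write_channel",
    "build_stack",
    "write_report",
    "read_report",
]

#: recognised channel roles; ``mineral`` is mandatory in every stack
CHANNEL_ROLES = ("mineral", "label1", "label2", "trap", "ap", "dapi", "gfp")

_SITES = ("femur", "vertebra")


@dataclass
class RasterImage:
    """A single-channel 2-D intensity raster with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError(f"raster must be at least 2x2, got {self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        return RasterImage(pixels=pixels, pixel_size_um=self.pixel_size_um)

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um


@dataclass
class ChannelStack:
    """Co-registered named channels of one bone section."""

    channels: dict[str, RasterImage]
    site: str = "femur"

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise ValueError(f"site must be one of {_SITES}, got {self.site!r}")
        if "mineral" not in self.channels:
            raise ValueError("a ChannelStack requires the mineral channel")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}; known: {CHANNEL_ROLES}")
        ref = self.channels["mineral"]
        for role, img in self.channels.items():
            if img.shape != ref.shape:
                raise ValueError(
                    f"channel {role!r} has shape {img.shape}, expected {ref.shape} (mineral)"
                )
            if img.pixel_size_um != ref.pixel_size_um:
                raise ValueError(f"channel {role!r} pixel size differs from mineral channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["mineral"].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels["mineral"].pixel_size_um

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def __getitem__(self, role: str) -> RasterImage:
        if role not in self.channels:
            raise KeyError(f"channel role {role!r} absent from stack")
        return self.channels[role]

    def subset(self, roles: list[str]) -> "ChannelStack":
        sub = {r: self.channels[r] for r in roles}
        if "mineral" not in sub:
            sub["mineral"] = self.channels["mineral"]
        return ChannelStack(channels=sub, site=self.site)

    def replace(self, **channels: RasterImage) -> "ChannelStack":
        new = dict(self.channels)
        new.update(channels)
        return ChannelStack(channels=new, site=self.site)

    def write(self, directory: str | Path) -> None:
        """Write one grayscale TIFF per channel into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for role, img in self.channels.items():
            write_channel(img, directory / f"{role}.tiff")

    @classmethod
    def read(
        cls, directory: str | Path, pixel_size_um: float, site: str = "femur"
    ) -> "ChannelStack":
        directory = Path(directory)
        images = {}
        for role in CHANNEL_ROLES:
            for ext in (".tiff", ".tif", ".png"):
                p = directory / f"{role}{ext}"
                if p.exists():
                    images[role] = read_channel(p, pixel_size_um)
                    break
        return build_stack(images, site)


def read_channel(path: str | Path, pixel_size_um: float) -> RasterImage:
    """Read one grayscale 8/16-bit channel file losslessly.

    Color (multi-channel) files are rejected: each fluorescence role must be
    exported as its own single-channel file.
    """
    path = Path(path)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(
            f"{path} is not single-channel grayscale (shape {arr.shape}); "
            "export each role as a separate grayscale file"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: expected 8- or 16-bit grayscale, got dtype {arr.dtype}")
    return RasterImage(pixels=arr, pixel_size_um=pixel_size_um)


def write_channel(image: RasterImage, path: str | Path) -> None:
    """Write a channel as grayscale TIFF or PNG (by extension), losslessly.

    Floating-point rasters are rounded to uint16; integer rasters keep dtype.
    """
    path = Path(path)
    arr = image.pixels
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def build_stack(images: Mapping[str, RasterImage], site: str = "femur") -> ChannelStack:
    """Validate a role->image mapping into a ChannelStack.

    Missing optional roles are simply absent; shape / pixel-size mismatches
    raise, naming the offending role.
    """
    return ChannelStack(channels=dict(images), site=site)


def write_report(report: HistomorphometryReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report; JSON keeps provenance, CSV is name,value,units rows.

    Absent measurements serialize as JSON ``null`` / empty CSV cell, never 0.
    """
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json())
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "value", "units"])
            for name, value, units in report.rows():
                w.writerow([name, "" if value is None else repr(float(value)), units])
    else:
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def read_report(path: str | Path) -> HistomorphometryReport:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rep = HistomorphometryReport()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                val = None if row["value"] == "" else float(row["value"])
                rep.update({row["name"]: val})
        return rep
    return HistomorphometryReport.from_json(path.read_text())
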