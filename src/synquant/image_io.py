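"""Calibrated multi-channel image container and TIFF/OME-TIFF I/O.

All downstream measurements are reported in physical units, so every image
carries its lateral pixel size (μm/pixel) and, for stacks, the axial step
(μm/slice).  Reading a file without any pixel-size metadata is an error
unless the caller supplies an explicit override — a silent 1 μm/px
assumption would corrupt every area threshold in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when an image's physical pixel size cannot be established."""


@dataclass
class CalibratedImage:
    """Multi-channel fluorescence image with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array, ``(channel, y, x)`` for planar images or
        ``(z, channel, y, x)`` for stacks.  Values are non-negative.
    pixel_size_xy
        Lateral pixel size in μm/pixel; strictly positive.
    channel_names
        One label per channel, e.g. ``["VGluT1", "PSD95", "PV"]``.
    z_step
        Axial slice spacing in μm, or ``None`` for planar images.
    bit_depth
        Acquisition bit depth (metadata only; pixels may be float after
        preprocessing).
    """

    pixels: np.ndarray
    pixel_size_xy: float
    channel_names: list[str] = field(default_factory=list)
    z_step: float | None = None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[np.newaxis]
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"pixels must be (c, y, x) or (z, c, y, x); got shape {self.pixels.shape}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        if not (self.pixel_size_xy > 0):
            raise CalibrationError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if self.z_step is not None and not (self.z_step > 0):
            raise CalibrationError(f"z_step must be > 0, got {self.z_step}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1] if self.is_stack else self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size_xy**2

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³ (stacks only)."""
        if self.z_step is None:
            raise ValueError("voxel_volume requires a z-calibrated stack")
        return self.pixel_size_xy**2 * self.z_step

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel: int | str) -> np.ndarray:
        """Return one channel: ``(y, x)`` plane or ``(z, y, x)`` stack."""
        c = self.channel_index(channel)
        return self.pixels[:, c] if self.is_stack else self.pixels[c]

    def with_channel(self, channel: int | str, data: np.ndarray) -> "CalibratedImage":
        """Copy of the image with one channel replaced."""
        c = self.channel_index(channel)
        px = self.pixels.astype(np.result_type(self.pixels, data), copy=True)
        if self.is_stack:
            px[:, c] = data
        else:
            px[c] = data
        return replace(self, pixels=px)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Extract the lateral pixel size in μm from OME metadata or TIFF tags."""
    if tif.ome_metadata:
        import re

        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
        if m:
            size = float(m.group(1))
            unit = re.search(r'PhysicalSizeXUnit="([^"]+)"', tif.ome_metadata)
            if unit and unit.group(1) in ("nm",):
                size *= 1e-3
            return size
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
            px = den / num  # size per pixel in resolution units
            unit_val = getattr(unit, "value", unit)
            if unit_val == 3:  # centimeter
                return px * 1e4
            if unit_val == 2:  # inch
                return px * 2.54e4
            # RESUNIT.NONE / absent: resolution tags carry no physical unit
    return None


def _z_step_from_tiff(tif: tifffile.TiffFile) -> float | None:
    if tif.ome_metadata:
        import re

        m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tif.ome_metadata)
        if m:
            return float(m.group(1))
    return None


def _channel_names_from_tiff(tif: tifffile.TiffFile) -> list[str]:
    if not tif.ome_metadata:
        return []
    import re

    return re.findall(r'<Channel[^>]*\bName="([^"]+)"', tif.ome_metadata)


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_names: list[str] | None = None,
    z_step_override: float | None = None,
) -> CalibratedImage:
    """Read a TIFF / OME-TIFF as a :class:`CalibratedImage`.

    The channel axis is normalized to ``(c, y, x)`` (planar) or
    ``(z, c, y, x)`` (stack).  An explicit ``pixel_size_override`` always
    wins over embedded metadata; absence of both raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        series = tif.series[0]
        axes = series.axes  # e.g. "CYX", "ZCYX", "YX"
        meta_px = _pixel_size_from_tiff(tif)
        meta_z = _z_step_from_tiff(tif)
        meta_channels = _channel_names_from_tiff(tif)
        bit_depth = int(series.dtype.itemsize * 8)

    pixel_size = pixel_size_override if pixel_size_override is not None else meta_px
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override given; refusing "
            "to assume a calibration"
        )
    z_step = z_step_override if z_step_override is not None else meta_z

    # Normalize axis order to (Z)CYX.
    axes = axes.replace("S", "C").replace("Q", "C")
    if set(axes) - set("ZCYX"):
        raise ValueError(f"unsupported TIFF axes {axes!r}")
    if "C" not in axes:
        data = data[..., np.newaxis, :, :] if "Z" in axes else data[np.newaxis]
        axes = axes[:-2] + "CYX"
    order = [axes.index(a) for a in ("Z", "C", "Y", "X") if a in axes]
    data = np.transpose(data, order)

    names = channel_names or meta_channels
    n_ch = data.shape[1] if data.ndim == 4 else data.shape[0]
    if len(names) != n_ch:
        names = []
    return CalibratedImage(
        pixels=data,
        pixel_size_xy=float(pixel_size),
        channel_names=names,
        z_step=z_step,
        bit_depth=bit_depth,
    )


def write_image(path: str | Path, img: CalibratedImage) -> None:
    """Write a :class:`CalibratedImage` as OME-TIFF with physical calibration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    axes = "ZCYX" if img.is_stack else "CYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": img.pixel_size_xy,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": img.pixel_size_xy,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(img.channel_names)},
    }
    if img.z_step is not None:
        metadata["PhysicalSizeZ"] = img.z_step
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, img.pixels, ome=True, metadata=metadata)


def write_label_map(path: str | Path, labels: np.ndarray, pixel_size_xy: float) -> None:
    """Write a label map as 16-bit TIFF (labels clipped at 65535)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.clip(labels, 0, np.iinfo(np.uint16).max).astype(np.uint16),
        resolution=(1.0 / pixel_size_xy, 1.0 / pixel_size_xy),
    )
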