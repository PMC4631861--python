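"""Calibrated multi-dimensional image stacks: TIFF round-trip and projections.

An :class:`ImageSeries` couples a ``(time, channel, z, y, x)`` pixel array
with its physical calibration (pixel size, z-spacing, frame times).  On disk
a series is a multi-page TIFF (channel varying fastest, then z, then time)
with a JSON sidecar carrying the calibration; pixel values are stored as
16-bit unsigned integers and converted to floats on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageSeries",
    "read_series",
    "write_series",
    "max_project",
    "central_slice",
    "sidecar_path",
]


@dataclass
class ImageSeries:
    """A calibrated image stack with axes ``(time, channel, z, y, x)``.

    Parameters
    ----------
    pixels
        Non-negative float array of shape ``(n_t, n_c, n_z, n_y, n_x)``.
    pixel_size_um
        Lateral pixel size in micrometres (must be positive).
    z_spacing_um
        Axial spacing between z-slices in micrometres.
    frame_times_s
        Acquisition time of each frame in seconds; length must equal the
        time-axis length.
    channel_names
        One name per channel.
    bleach_frame_index
        Index of the photobleach frame, or ``None`` for non-FRAP stacks.
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    frame_times_s: list[float]
    channel_names: list[str]
    bleach_frame_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must have 5 axes (t, c, z, y, x); got {self.pixels.ndim}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")
        self.frame_times_s = [float(t) for t in self.frame_times_s]
        self.channel_names = list(self.channel_names)
        if len(self.frame_times_s) != self.pixels.shape[0]:
            raise ValueError(
                f"frame_times_s has {len(self.frame_times_s)} entries but the "
                f"time axis has length {self.pixels.shape[0]}"
            )
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries but the "
                f"channel axis has length {self.pixels.shape[1]}"
            )
        if self.bleach_frame_index is not None and not (
            0 <= self.bleach_frame_index < self.pixels.shape[0]
        ):
            raise ValueError("bleach_frame_index outside the time axis")

    @property
    def n_t(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_c(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)

    def metadata(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "z_spacing_um": self.z_spacing_um,
            "frame_times_s": self.frame_times_s,
            "channel_names": self.channel_names,
            "bleach_frame_index": self.bleach_frame_index,
            "n_z": self.n_z,
        }


def sidecar_path(path: str | Path) -> Path:
    """JSON metadata file accompanying a TIFF at *path*."""
    return Path(path).with_suffix(".json")


def write_series(series: ImageSeries, path: str | Path) -> Path:
    """Write *series* as a multi-page uint16 TIFF plus a JSON sidecar.

    Page order is channel-fastest: page ``(t * n_z + z) * n_c + c`` holds
    timepoint *t*, slice *z*, channel *c*.  Values are rounded and clipped
    to the uint16 range.
    """
    path = Path(path)
    data = np.transpose(series.pixels, (0, 2, 1, 3, 4))  # (t, z, c, y, x)
    pages = data.reshape(-1, *series.shape_yx)
    pages = np.clip(np.rint(pages), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, pages)
    with open(sidecar_path(path), "w") as fh:
        json.dump(series.metadata(), fh, indent=1)
    return path


def read_series(path: str | Path, metadata: dict | None = None) -> ImageSeries:
    """Read a multi-page TIFF written by :func:`write_series`.

    Calibration is taken from *metadata* if given, otherwise from the JSON
    sidecar; it is never silently defaulted.  Raises ``ValueError`` when the
    page count is inconsistent with the declared geometry.
    """
    path = Path(path)
    if metadata is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise FileNotFoundError(
                f"no metadata supplied and sidecar {sc} does not exist"
            )
        with open(sc) as fh:
            metadata = json.load(fh)
    required = ("pixel_size_um", "z_spacing_um", "frame_times_s", "channel_names", "n_z")
    missing = [k for k in required if k not in metadata]
    if missing:
        raise ValueError(f"metadata missing required keys: {missing}")

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_t = len(metadata["frame_times_s"])
    n_c = len(metadata["channel_names"])
    n_z = int(metadata["n_z"])
    expected = n_t * n_c * n_z
    if pages.shape[0] != expected:
        raise ValueError(
            f"page count mismatch: expected {expected} "
            f"({n_t} t x {n_z} z x {n_c} c) but file holds {pages.shape[0]}"
        )
    data = pages.reshape(n_t, n_z, n_c, *pages.shape[1:]).astype(float)
    return ImageSeries(
        pixels=np.transpose(data, (0, 2, 1, 3, 4)),
        pixel_size_um=float(metadata["pixel_size_um"]),
        z_spacing_um=float(metadata["z_spacing_um"]),
        frame_times_s=list(metadata["frame_times_s"]),
        channel_names=list(metadata["channel_names"]),
        bleach_frame_index=metadata.get("bleach_frame_index"),
    )


def max_project(series: ImageSeries) -> ImageSeries:
    """Maximum-intensity projection over z; calibration is preserved."""
    return ImageSeries(
        pixels=series.pixels.max(axis=2, keepdims=True),
        pixel_size_um=series.pixel_size_um,
        z_spacing_um=series.z_spacing_um,
        frame_times_s=series.frame_times_s,
        channel_names=series.channel_names,
        bleach_frame_index=series.bleach_frame_index,
    )


def central_slice(
    series: ImageSeries,
    window: tuple[int, int, int, int] | None = None,
) -> tuple[ImageSeries, int]:
    """Select the z-slice with the largest summed intensity in *window*.

    *window* is a pixel box ``(row0, row1, col0, col1)`` (half-open); ``None``
    means the whole frame.  The sum pools all timepoints and channels.  Ties
    break to the lowest index.  Returns the single-z series and the index.
    """
    if window is None:
        sub = series.pixels
    else:
        r0, r1, c0, c1 = window
        sub = series.pixels[:, :, :, r0:r1, c0:c1]
        if sub.shape[3] == 0 or sub.shape[4] == 0:
            raise ValueError(f"empty analysis window {window}")
    per_slice = sub.sum(axis=(0, 1, 3, 4))
    z_index = int(np.argmax(per_slice))  # argmax returns the first maximum
    return (
        ImageSeries(
            pixels=series.pixels[:, :, z_index : z_index + 1],
            pixel_size_um=series.pixel_size_um,
            z_spacing_um=series.z_spacing_um,
            frame_times_s=series.frame_times_s,
            channel_names=series.channel_names,
            bleach_frame_index=series.bleach_frame_index,
        ),
        z_index,
    )
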