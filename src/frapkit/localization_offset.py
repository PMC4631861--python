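"""Sub-pixel offset between the recovering green and red centrosomal signals.

The measurement follows the standard-resolution recipe: crop an analysis
window around the centrosome, pick the most central z-slice per channel,
scale the slice up fivefold (bilinear), threshold, take the intensity-
weighted centre of mass of each channel, correct the red centroid with the
bead registration model, and express the green position relative to the red
signal at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .image_io import ImageSeries
from .registration import RegistrationModel, apply_registration

__all__ = [
    "EmptySignalError",
    "CentroidResult",
    "OffsetMeasurement",
    "OffsetSummary",
    "upscale",
    "compute_centroid",
    "measure_pair_offset",
    "aggregate_offsets",
    "window_around",
]


class EmptySignalError(ValueError):
    """No pixel exceeded the threshold — the signal is absent, not malformed."""


@dataclass(frozen=True)
class CentroidResult:
    position_um: tuple[float, float]
    threshold_used: float
    n_pixels_above: int
    z_index: int


@dataclass(frozen=True)
class OffsetMeasurement:
    """Green position relative to the corrected red position (red at origin)."""

    green_centroid: CentroidResult
    red_centroid_corrected: CentroidResult
    displacement_um: tuple[float, float]
    distance_um: float
    timepoint_s: float


@dataclass(frozen=True)
class OffsetSummary:
    mean_distance_um: float
    median_distance_um: float
    n: int
    table: pd.DataFrame  # columns: id, dx_um, dy_um, distance_um, t_s


def upscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear upscaling by an integer factor; the grid extent is preserved.

    Output pixel *i* samples the input at ``(i + 0.5) / factor - 0.5`` in
    input pixel coordinates, so the effective pixel size is divided by
    ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return np.asarray(image, dtype=float).copy()
    image = np.asarray(image, dtype=float)
    out_shape = (image.shape[0] * factor, image.shape[1] * factor)
    return resize(image, out_shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def compute_centroid(
    image: np.ndarray,
    pixel_size_um: float = 1.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
    *,
    threshold: float | None = None,
    threshold_frac: float = 0.5,
    background: float | None = None,
    z_index: int = 0,
) -> CentroidResult:
    """Intensity-weighted centre of mass of the above-threshold pixels.

    When no explicit threshold is given it defaults to
    ``background + threshold_frac * (max - background)`` with the background
    estimated as the median of the window border.  Weights are the
    background-subtracted intensities, clipped at zero.  The returned
    position is ``origin_um + index * pixel_size_um`` in ``(x, y)`` order.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("compute_centroid expects a non-empty 2-D window")
    if background is None:
        if min(image.shape) >= 3:
            border = np.concatenate(
                [image[0], image[-1], image[1:-1, 0], image[1:-1, -1]]
            )
            background = float(np.median(border))
        else:
            background = float(image.min())
    if threshold is None:
        threshold = background + threshold_frac * (image.max() - background)
    mask = image > threshold
    if not mask.any():
        raise EmptySignalError(
            f"no pixel above threshold {threshold:.4g} (window max {image.max():.4g})"
        )
    weights = np.clip(image - background, 0.0, None) * mask
    total = weights.sum()
    if total <= 0:
        # explicit threshold below background: fall back to raw intensities
        weights = image * mask
        total = weights.sum()
    if total <= 0:
        raise EmptySignalError("above-threshold pixels carry no positive weight")
    rr, cc = np.nonzero(mask)
    w = weights[rr, cc]
    row = float((w * rr).sum() / total)
    col = float((w * cc).sum() / total)
    return CentroidResult(
        position_um=(origin_um[0] + col * pixel_size_um, origin_um[1] + row * pixel_size_um),
        threshold_used=float(threshold),
        n_pixels_above=int(mask.sum()),
        z_index=z_index,
    )


def window_around(
    center_um,
    half_width_um: float,
    pixel_size_um: float,
    shape_px: tuple[int, int],
) -> tuple[int, int, int, int]:
    """Pixel box ``(row0, row1, col0, col1)`` around a um position, clipped."""
    x, y = center_um
    half = int(round(half_width_um / pixel_size_um))
    r = int(round(y / pixel_size_um))
    c = int(round(x / pixel_size_um))
    return (
        max(0, r - half),
        min(shape_px[0], r + half + 1),
        max(0, c - half),
        min(shape_px[1], c + half + 1),
    )


def _nearest_postbleach_frame(series: ImageSeries, t_query_s: float) -> int:
    times = np.asarray(series.frame_times_s)
    candidates = np.arange(len(times))
    if series.bleach_frame_index is not None:
        candidates = candidates[candidates > series.bleach_frame_index]
        if candidates.size == 0:
            raise ValueError("series has no post-bleach frames")
    return int(candidates[np.argmin(np.abs(times[candidates] - t_query_s))])


def _channel_centroid(
    series: ImageSeries,
    channel: int,
    t_idx: int,
    window: tuple[int, int, int, int],
    upscale_factor: int,
    threshold_frac: float,
) -> CentroidResult:
    r0, r1, c0, c1 = window
    stack = series.pixels[t_idx, channel, :, r0:r1, c0:c1]
    if stack.shape[1] == 0 or stack.shape[2] == 0:
        raise ValueError(f"empty analysis window {window}")
    z_index = int(np.argmax(stack.sum(axis=(1, 2))))  # most central slice
    up = upscale(stack[z_index], upscale_factor)
    p = series.pixel_size_um
    fine = p / upscale_factor
    # centre of upscaled pixel 0 in global um coordinates
    origin = ((c0 - 0.5) * p + 0.5 * fine, (r0 - 0.5) * p + 0.5 * fine)
    res = compute_centroid(
        up, pixel_size_um=fine, origin_um=origin, threshold_frac=threshold_frac,
        z_index=z_index,
    )
    return res


def measure_pair_offset(
    series: ImageSeries,
    window: tuple[int, int, int, int],
    t_query_s: float,
    model: RegistrationModel | None = None,
    *,
    green_channel: int | str = "green",
    red_channel: int | str = "red",
    upscale_factor: int = 5,
    threshold_frac: float = 0.5,
) -> OffsetMeasurement:
    """Measure the corrected green-red centroid displacement at one timepoint.

    The frame nearest to ``t_query_s`` among the post-bleach frames is used
    and its actual time recorded.  Each channel is centroided independently
    on its own most central z-slice; the red centroid is corrected by the
    registration model (if given) before the displacement (green relative to
    red at the origin) is formed.
    """
    gi = series.channel_index(green_channel)
    ri = series.channel_index(red_channel)
    t_idx = _nearest_postbleach_frame(series, t_query_s)
    results = {}
    for name, ci in (("green", gi), ("red", ri)):
        try:
            results[name] = _channel_centroid(
                series, ci, t_idx, window, upscale_factor, threshold_frac
            )
        except EmptySignalError as exc:
            raise EmptySignalError(f"no recovery signal in the {name} channel: {exc}")
    green = results["green"]
    red = results["red"]
    red_pos = np.asarray(red.position_um)
    if model is not None:
        red_pos = apply_registration(red_pos, model)
    red_corr = CentroidResult(
        position_um=(float(red_pos[0]), float(red_pos[1])),
        threshold_used=red.threshold_used,
        n_pixels_above=red.n_pixels_above,
        z_index=red.z_index,
    )
    disp = np.asarray(green.position_um) - red_pos
    return OffsetMeasurement(
        green_centroid=green,
        red_centroid_corrected=red_corr,
        displacement_um=(float(disp[0]), float(disp[1])),
        distance_um=float(np.hypot(disp[0], disp[1])),
        timepoint_s=float(series.frame_times_s[t_idx]),
    )


def aggregate_offsets(measurements: list[OffsetMeasurement]) -> OffsetSummary:
    """Summarise per-centrosome displacements (red at the origin)."""
    if not measurements:
        raise ValueError("aggregate_offsets requires at least one measurement")
    table = pd.DataFrame(
        {
            "id": np.arange(len(measurements)),
            "dx_um": [m.displacement_um[0] for m in measurements],
            "dy_um": [m.displacement_um[1] for m in measurements],
            "distance_um": [m.distance_um for m in measurements],
            "t_s": [m.timepoint_s for m in measurements],
        }
    )
    return OffsetSummary(
        mean_distance_um=float(table["distance_um"].mean()),
        median_distance_um=float(table["distance_um"].median()),
        n=len(measurements),
        table=table,
    )
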