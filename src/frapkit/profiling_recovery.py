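"""Radial intensity profiles and FRAP recovery-over-time curves.

Radial profiling measures the mean intensity in concentric rings (default
spacing 0.028 um out to 3.02 um) about a signal centre; profiles are then
background-subtracted, peak-normalised to 1 and mirrored about r = 0 for
display.  Recovery curves sum each channel over a reference-channel ROI
(all pixels above mean + 2 SD of the reference frame), subtract the local
cytoplasmic background and normalise to the mean pre-bleach value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .image_io import ImageSeries, max_project

__all__ = [
    "RadialProfile",
    "PairedProfiles",
    "RecoveryCurve",
    "NoReferenceSignalError",
    "radial_profile",
    "finalize_profile",
    "average_and_offset_profiles",
    "recovery_roi",
    "recovery_curve",
    "annulus_mask",
]

DEFAULT_RING_SPACING_UM = 0.028
DEFAULT_RING_EXTENT_UM = 3.02


class NoReferenceSignalError(ValueError):
    pass


@dataclass(frozen=True)
class RadialProfile:
    """Ring-averaged intensity versus radius.

    ``mean_intensity[k]`` is the mean over pixels whose centre radius falls
    in ``[k * spacing, (k + 1) * spacing)``; rings with no pixels are NaN
    (missing, not zero).  ``mirrored_*`` fields are populated by
    :func:`finalize_profile`.
    """

    radii_um: np.ndarray  # ring centres
    mean_intensity: np.ndarray
    spacing_um: float
    background_subtracted: bool = False
    normalised: bool = False
    mirrored_axis_um: np.ndarray | None = None
    mirrored_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii_um", np.asarray(self.radii_um, dtype=float))
        object.__setattr__(self, "mean_intensity", np.asarray(self.mean_intensity, dtype=float))
        if self.radii_um.shape != self.mean_intensity.shape:
            raise ValueError("radii_um and mean_intensity must have matching shapes")
        if len(self.radii_um) > 1:
            steps = np.diff(self.radii_um)
            if not np.allclose(steps, self.spacing_um, rtol=1e-6):
                raise ValueError("ring spacing is not uniform")


@dataclass(frozen=True)
class PairedProfiles:
    """Channel-averaged display profiles on a shared axis, red shifted."""

    green_axis_um: np.ndarray
    green_mean: np.ndarray
    red_axis_um: np.ndarray
    red_mean: np.ndarray
    offset_um: float


@dataclass(frozen=True)
class RecoveryCurve:
    times_s: np.ndarray
    green_norm: np.ndarray
    red_norm: np.ndarray
    roi_n_pixels: int
    pre_bleach_values: tuple[float, float]  # (green, red), raw units

    def __post_init__(self) -> None:
        if self.roi_n_pixels < 1:
            raise ValueError("roi_n_pixels must be >= 1")


def radial_profile(
    image: np.ndarray,
    center_um,
    pixel_size_um: float,
    spacing_um: float = DEFAULT_RING_SPACING_UM,
    extent_um: float = DEFAULT_RING_EXTENT_UM,
) -> RadialProfile:
    """Mean intensity per concentric ring about ``center_um`` (x, y in um).

    Pixels are assigned to rings by their centre radius (no area weighting).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("radial_profile expects a 2-D image")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    x0, y0 = float(center_um[0]), float(center_um[1])
    ex = (image.shape[1] - 1) * pixel_size_um
    ey = (image.shape[0] - 1) * pixel_size_um
    if not (0 <= x0 <= ex and 0 <= y0 <= ey):
        raise ValueError(f"center ({x0}, {y0}) um lies outside the image")

    n_rings = int(np.ceil(extent_um / spacing_um - 1e-9))
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    r = np.hypot(xx * pixel_size_um - x0, yy * pixel_size_um - y0)
    idx = np.floor(r / spacing_um).astype(int)
    inside = idx < n_rings
    sums = np.bincount(idx[inside], weights=image[inside], minlength=n_rings)
    counts = np.bincount(idx[inside], minlength=n_rings)
    means = np.full(n_rings, np.nan)
    nonzero = counts > 0
    means[nonzero] = sums[nonzero] / counts[nonzero]
    radii = (np.arange(n_rings) + 0.5) * spacing_um
    return RadialProfile(radii_um=radii, mean_intensity=means, spacing_um=spacing_um)


def finalize_profile(profile: RadialProfile, cytosolic_background: float) -> RadialProfile:
    """Background-subtract, peak-normalise to 1 and mirror about r = 0."""
    if cytosolic_background < 0:
        raise ValueError("cytosolic_background must be non-negative")
    vals = profile.mean_intensity - cytosolic_background
    peak = np.nanmax(vals) if np.any(np.isfinite(vals)) else np.nan
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("profile has no positive peak after background subtraction")
    norm = vals / peak
    mirrored = np.concatenate([norm[::-1], norm[1:]])
    # display axis: ring k sits at signed radius k * spacing so the mirrored
    # profile is exactly symmetric about 0
    edges = np.arange(len(norm)) * profile.spacing_um
    axis = np.concatenate([-edges[::-1], edges[1:]])
    return RadialProfile(
        radii_um=profile.radii_um,
        mean_intensity=norm,
        spacing_um=profile.spacing_um,
        background_subtracted=True,
        normalised=True,
        mirrored_axis_um=axis,
        mirrored_intensity=mirrored,
    )


def average_and_offset_profiles(
    green_profiles: list[RadialProfile],
    red_profiles: list[RadialProfile],
    mean_offset_um: float,
    min_profiles: int = 10,
) -> PairedProfiles:
    """Average finalized profiles per channel and shift the red axis.

    All profiles must share the same ring grid and have been through
    :func:`finalize_profile`.  ``min_profiles`` defaults to the analysis
    practice of averaging at least 10 centrosomes per channel.
    """
    for name, profs in (("green", green_profiles), ("red", red_profiles)):
        if len(profs) < min_profiles:
            raise ValueError(
                f"{name} channel has {len(profs)} profiles; {min_profiles} required"
            )
        for p in profs:
            if p.mirrored_intensity is None:
                raise ValueError(f"{name} profiles must be finalized before averaging")
            if p.radii_um.shape != profs[0].radii_um.shape or not np.allclose(
                p.radii_um, profs[0].radii_um
            ):
                raise ValueError("mismatched ring grids between profiles")
    ga, ra = green_profiles[0].radii_um, red_profiles[0].radii_um
    if ga.shape != ra.shape or not np.allclose(ga, ra):
        raise ValueError("mismatched ring grids between channels")

    g = np.mean([p.mirrored_intensity for p in green_profiles], axis=0)
    r = np.mean([p.mirrored_intensity for p in red_profiles], axis=0)
    axis = green_profiles[0].mirrored_axis_um
    return PairedProfiles(
        green_axis_um=axis,
        green_mean=g,
        red_axis_um=axis + mean_offset_um,
        red_mean=r,
        offset_um=float(mean_offset_um),
    )


def recovery_roi(reference_image: np.ndarray) -> np.ndarray:
    """ROI mask: pixels above mean + 2 SD of the reference image."""
    img = np.asarray(reference_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty reference image")
    mask = img > img.mean() + 2.0 * img.std()
    if not mask.any():
        raise NoReferenceSignalError(
            "no reference signal: no pixel above mean + 2 SD"
        )
    return mask


def annulus_mask(
    shape_px: tuple[int, int],
    center_um,
    pixel_size_um: float,
    r_inner_um: float = 1.8,
    r_outer_um: float = 2.4,
) -> np.ndarray:
    """Background annulus around the centrosome centre (default 1.8-2.4 um)."""
    yy, xx = np.mgrid[0 : shape_px[0], 0 : shape_px[1]]
    r = np.hypot(xx * pixel_size_um - center_um[0], yy * pixel_size_um - center_um[1])
    return (r >= r_inner_um) & (r < r_outer_um)


def recovery_curve(
    series: ImageSeries,
    mask: np.ndarray,
    background_region: np.ndarray,
    *,
    green_channel: int | str = "green",
    red_channel: int | str = "red",
) -> RecoveryCurve:
    """Background-subtracted, pre-bleach-normalised ROI sums per timepoint.

    Per timepoint and channel (on the max projection):
    ``sum over mask - mean(background region) * mask size``, then divided by
    the mean of the pre-bleach values of that channel.
    """
    mask = np.asarray(mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if not background_region.any():
        raise ValueError("background region is empty")
    if series.bleach_frame_index is None:
        raise ValueError("recovery_curve requires bleach_frame_index on the series")
    if series.bleach_frame_index < 1:
        raise ValueError("at least one pre-bleach frame is required")

    proj = max_project(series).pixels[:, :, 0]  # (t, c, y, x)
    gi = series.channel_index(green_channel)
    ri = series.channel_index(red_channel)
    n_px = int(mask.sum())
    values = np.empty((series.n_t, 2))
    for t in range(series.n_t):
        for out_idx, ci in enumerate((gi, ri)):
            frame = proj[t, ci]
            bg_per_px = frame[background_region].mean()
            values[t, out_idx] = frame[mask].sum() - bg_per_px * n_px

    pre = values[: series.bleach_frame_index].mean(axis=0)
    if np.any(pre <= 0):
        raise ValueError("pre-bleach mean is non-positive; cannot normalise")
    norm = values / pre
    return RecoveryCurve(
        times_s=np.asarray(series.frame_times_s),
        green_norm=norm[:, 0],
        red_norm=norm[:, 1],
        roi_n_pixels=n_px,
        pre_bleach_values=(float(pre[0]), float(pre[1])),
    )
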