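"""Synthetic two-channel fluorescence microscopy scenes with known ground truth.

Two scene families are generated:

* **bead fields** — sub-resolution fiducial beads imaged in both channels,
  where the red channel is displaced from the green by a systematic shift
  plus independent per-bead jitter.  These drive the channel-registration
  stage.
* **FRAP series** — a centrosome-like scene with a broad matrix signal in
  the green channel and one or two tight foci in the red channel, bleached
  at a stated frame and recovering exponentially, with the recovering red
  centre displaced from the recovering green centre by a known offset.

The point-spread function is an isotropic 2-D Gaussian per z-slice, rendered
by exact pixel integration (difference of error functions), with a Gaussian
amplitude decay away from the emitter's focal plane.  Photon flux is
conserved for emitters away from the image border.  Noise is
Poisson(signal + background) shot noise plus additive Gaussian read noise,
both switchable.  All randomness flows from a single seed in the scene spec.

Coordinates are continuous positions in micrometres, ``(x, y)`` order, with
the origin at the centre of pixel ``(0, 0)``; pixel indexing is row-major so
``x`` maps to columns and ``y`` to rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import erf

from .image_io import ImageSeries

__all__ = [
    "SceneSpec",
    "BeadFieldTruth",
    "CentrosomeTruth",
    "generate_bead_field",
    "generate_frap_series",
    "bead_grid_positions",
    "simulate_foci_dataset",
    "save_truth",
    "load_truth",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class SceneSpec:
    """Acquisition geometry, optics and noise parameters for one scene.

    Defaults mirror a spinning-disk acquisition: 0.105 um pixels and five
    z-slices spaced 0.5 um apart.
    """

    image_shape_px: tuple[int, int] = (96, 96)  # (rows, cols)
    pixel_size_um: float = 0.105
    n_z: int = 5
    z_spacing_um: float = 0.5
    frame_times_s: tuple[float, ...] = (0.0,)
    bleach_frame_index: int | None = None
    psf_sigma_um: float = 0.12
    psf_z_sigma_um: float = 0.8
    photons_per_emitter: float = 20000.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape_px", tuple(int(v) for v in self.image_shape_px))
        object.__setattr__(self, "frame_times_s", tuple(float(t) for t in self.frame_times_s))
        if len(self.image_shape_px) != 2 or min(self.image_shape_px) < 1:
            raise ValueError("image_shape_px must be a positive integer pair")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")
        if len(self.frame_times_s) == 0:
            raise ValueError("frame_times_s must be non-empty")
        diffs = np.diff(self.frame_times_s)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if self.bleach_frame_index is not None and not (
            0 <= self.bleach_frame_index < len(self.frame_times_s)
        ):
            raise ValueError("bleach_frame_index outside the frame range")
        if self.psf_sigma_um <= 0 or self.psf_z_sigma_um <= 0:
            raise ValueError("PSF widths must be positive")
        if self.photons_per_emitter <= 0:
            raise ValueError("photons_per_emitter must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def field_extent_um(self) -> tuple[float, float]:
        """(x, y) extent covered by pixel centres."""
        rows, cols = self.image_shape_px
        return ((cols - 1) * self.pixel_size_um, (rows - 1) * self.pixel_size_um)


@dataclass(frozen=True)
class BeadFieldTruth:
    """Ground truth for one fiducial-bead calibration image."""

    bead_positions_um: tuple[tuple[float, float], ...]
    true_shift_um: tuple[float, float]  # systematic red-minus-green displacement
    per_bead_jitter_sd_um: float = 0.0

    def __post_init__(self) -> None:
        pos = tuple((float(x), float(y)) for x, y in self.bead_positions_um)
        object.__setattr__(self, "bead_positions_um", pos)
        object.__setattr__(self, "true_shift_um", tuple(float(v) for v in self.true_shift_um))
        if not np.all(np.isfinite(self.true_shift_um)):
            raise ValueError("true_shift_um must be finite")
        if self.per_bead_jitter_sd_um < 0:
            raise ValueError("per_bead_jitter_sd_um must be non-negative")


@dataclass(frozen=True)
class CentrosomeTruth:
    """Ground truth for one centrosome FRAP scene.

    ``recovery_rate_per_s``, ``recovered_fraction`` and
    ``recovery_delay_frame`` are per-channel pairs in ``(green, red)`` order.
    The recovering red signal is centred at
    ``pcm_center_um + channel_offset_um``; the recovering green signal at
    ``pcm_center_um``.  When ``pcm_sigma_end_um`` is set, the green matrix
    signal recovers narrow and widens linearly to that value over the
    post-bleach frames (steady-state width before the bleach).
    """

    pcm_center_um: tuple[float, float]
    mother_pos_um: tuple[float, float]
    daughter_pos_um: tuple[float, float] | None
    pcm_sigma_um: float
    channel_offset_um: tuple[float, float]
    recovery_rate_per_s: tuple[float, float]
    recovered_fraction: tuple[float, float]
    recovery_delay_frame: tuple[int | None, int | None] = (None, None)
    pcm_sigma_end_um: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pcm_center_um", tuple(float(v) for v in self.pcm_center_um))
        object.__setattr__(self, "mother_pos_um", tuple(float(v) for v in self.mother_pos_um))
        if self.daughter_pos_um is not None:
            object.__setattr__(
                self, "daughter_pos_um", tuple(float(v) for v in self.daughter_pos_um)
            )
        object.__setattr__(
            self, "channel_offset_um", tuple(float(v) for v in self.channel_offset_um)
        )
        object.__setattr__(
            self, "recovery_rate_per_s", tuple(float(v) for v in self.recovery_rate_per_s)
        )
        object.__setattr__(
            self, "recovered_fraction", tuple(float(v) for v in self.recovered_fraction)
        )
        object.__setattr__(
            self,
            "recovery_delay_frame",
            tuple(None if v is None else int(v) for v in self.recovery_delay_frame),
        )
        if self.pcm_sigma_um <= 0:
            raise ValueError("pcm_sigma_um must be positive")
        if any(r <= 0 for r in self.recovery_rate_per_s):
            raise ValueError("recovery_rate_per_s entries must be positive")
        if any(not (0.0 <= f <= 1.0) for f in self.recovered_fraction):
            raise ValueError("recovered_fraction entries must lie in [0, 1]")
        if self.pcm_sigma_end_um is not None and self.pcm_sigma_end_um <= 0:
            raise ValueError("pcm_sigma_end_um must be positive when set")


# ---------------------------------------------------------------------------
# PSF rendering


def _pixel_fractions(indices: np.ndarray, center_um: float, sigma_um: float,
                     pixel_size_um: float) -> np.ndarray:
    """Fraction of a unit Gaussian falling into each pixel along one axis."""
    lo = (indices * pixel_size_um - pixel_size_um / 2 - center_um) / (sigma_um * _SQRT2)
    hi = (indices * pixel_size_um + pixel_size_um / 2 - center_um) / (sigma_um * _SQRT2)
    return 0.5 * (erf(hi) - erf(lo))


def _z_weights(spec: SceneSpec, focal_z_um: float) -> np.ndarray:
    z = np.arange(spec.n_z) * spec.z_spacing_um
    w = np.exp(-((z - focal_z_um) ** 2) / (2.0 * spec.psf_z_sigma_um**2))
    return w / w.sum()


def _render_emitters(spec: SceneSpec, emitters, focal_z_um: float | None = None) -> np.ndarray:
    """Render emitters ``(x_um, y_um, photons, sigma_um)`` into a (z, y, x) stack."""
    rows, cols = spec.image_shape_px
    out = np.zeros((spec.n_z, rows, cols))
    if focal_z_um is None:
        focal_z_um = (spec.n_z - 1) / 2.0 * spec.z_spacing_um
    wz = _z_weights(spec, focal_z_um)
    p = spec.pixel_size_um
    for x0, y0, photons, sigma in emitters:
        if photons <= 0:
            continue
        half = max(3, int(np.ceil(6.0 * sigma / p)))
        c0 = int(round(x0 / p))
        r0 = int(round(y0 / p))
        cc = np.arange(max(0, c0 - half), min(cols, c0 + half + 1))
        rr = np.arange(max(0, r0 - half), min(rows, r0 + half + 1))
        if cc.size == 0 or rr.size == 0:
            continue
        fx = _pixel_fractions(cc, x0, sigma, p)
        fy = _pixel_fractions(rr, y0, sigma, p)
        spot = photons * np.outer(fy, fx)
        out[:, rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1] += wz[:, None, None] * spot
    return out


def _apply_noise(clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = clean + spec.background_level
    if spec.shot_noise:
        img = rng.poisson(img).astype(float)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# Bead fields


def _check_in_field(positions: np.ndarray, spec: SceneSpec, what: str) -> None:
    ex, ey = spec.field_extent_um
    bad = (positions[:, 0] < 0) | (positions[:, 0] > ex) | (positions[:, 1] < 0) | (
        positions[:, 1] > ey
    )
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{what} position {tuple(positions[idx])} um lies outside the "
            f"field (0..{ex:.3f}, 0..{ey:.3f}) um"
        )


def generate_bead_field(
    spec: SceneSpec, truth: BeadFieldTruth
) -> tuple[ImageSeries, BeadFieldTruth]:
    """Render a two-channel, single-timepoint bead-calibration image.

    Green beads sit at ``truth.bead_positions_um``; red beads at the same
    positions plus ``truth.true_shift_um`` plus independent Gaussian jitter.
    Beads must fit inside the field and be separated by at least four PSF
    widths so downstream matching is unambiguous.
    """
    pos = np.asarray(truth.bead_positions_um, dtype=float)
    if pos.size == 0:
        raise ValueError("bead field must contain at least one bead")
    _check_in_field(pos, spec, "bead")
    if len(pos) > 1:
        from scipy.spatial.distance import pdist

        if pdist(pos).min() < 4.0 * spec.psf_sigma_um:
            raise ValueError(
                "bead positions violate the minimum separation of 4 x psf_sigma_um"
            )
    rng = np.random.default_rng(spec.rng_seed)
    jitter = rng.normal(0.0, truth.per_bead_jitter_sd_um, size=pos.shape)
    red_pos = pos + np.asarray(truth.true_shift_um) + jitter
    _check_in_field(red_pos, spec, "red-channel bead")

    photons = spec.photons_per_emitter
    sigma = spec.psf_sigma_um
    green = _render_emitters(spec, [(x, y, photons, sigma) for x, y in pos])
    red = _render_emitters(spec, [(x, y, photons, sigma) for x, y in red_pos])
    green = _apply_noise(green, spec, rng)
    red = _apply_noise(red, spec, rng)

    series = ImageSeries(
        pixels=np.stack([green, red])[None],  # (1, 2, z, y, x)
        pixel_size_um=spec.pixel_size_um,
        z_spacing_um=spec.z_spacing_um,
        frame_times_s=list(spec.frame_times_s)[:1],
        channel_names=["green", "red"],
    )
    return series, truth


def bead_grid_positions(
    spec: SceneSpec,
    n_beads: int,
    rng: np.random.Generator,
    margin_um: float = 1.0,
    jitter_um: float | None = None,
) -> tuple[tuple[float, float], ...]:
    """Well-separated bead positions on a jittered grid inside the field."""
    ex, ey = spec.field_extent_um
    side = int(np.ceil(np.sqrt(n_beads)))
    xs = np.linspace(margin_um, ex - margin_um, side)
    ys = np.linspace(margin_um, ey - margin_um, side)
    pitch = min(np.diff(xs).min() if side > 1 else ex, np.diff(ys).min() if side > 1 else ey)
    if jitter_um is None:
        jitter_um = max(0.0, (pitch - 5.0 * spec.psf_sigma_um) / 2.0) * 0.6
    # keep jittered beads clear of the detector border-exclusion zone
    jitter_um = min(jitter_um, max(0.0, margin_um - 0.5))
    grid = [(x, y) for y in ys for x in xs][:n_beads]
    grid = np.asarray(grid)
    grid += rng.uniform(-jitter_um, jitter_um, size=grid.shape)
    return tuple((float(x), float(y)) for x, y in grid)


# ---------------------------------------------------------------------------
# FRAP series


def _recovery_amplitude(
    frame_idx: int,
    spec: SceneSpec,
    rate: float,
    fraction: float,
    delay_frame: int | None,
) -> float:
    """Closed-form signal amplitude relative to the pre-bleach steady state."""
    assert spec.bleach_frame_index is not None
    if frame_idx < spec.bleach_frame_index:
        return 1.0
    if delay_frame is not None and frame_idx < delay_frame:
        return 0.0
    t0 = spec.frame_times_s[delay_frame if delay_frame is not None else spec.bleach_frame_index]
    t = spec.frame_times_s[frame_idx]
    return fraction * (1.0 - np.exp(-rate * (t - t0)))


def _pcm_sigma_at(frame_idx: int, spec: SceneSpec, truth: CentrosomeTruth) -> float:
    if truth.pcm_sigma_end_um is None:
        return truth.pcm_sigma_um
    assert spec.bleach_frame_index is not None
    if frame_idx < spec.bleach_frame_index:
        return truth.pcm_sigma_end_um  # steady state = fully spread
    n_post = len(spec.frame_times_s) - 1 - spec.bleach_frame_index
    if n_post <= 0:
        return truth.pcm_sigma_um
    frac = (frame_idx - spec.bleach_frame_index) / n_post
    return truth.pcm_sigma_um + frac * (truth.pcm_sigma_end_um - truth.pcm_sigma_um)


def generate_frap_series(
    spec: SceneSpec,
    truth: CentrosomeTruth,
    microscope_shift_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[ImageSeries, CentrosomeTruth]:
    """Render a two-channel FRAP time series with a known inter-channel offset.

    Channel 0 ("green") carries the broad matrix signal centred at
    ``truth.pcm_center_um``; channel 1 ("red") carries the tight foci.
    Before the bleach frame both channels show their steady state; from the
    bleach frame on, amplitudes follow
    ``fraction * (1 - exp(-rate * (t - t_bleach)))`` per channel, optionally
    delayed to a stated frame.  The recovering red focus is centred at
    ``pcm_center_um + channel_offset_um``.  ``microscope_shift_um`` is an
    instrument misalignment added to every red-channel position (what the
    registration stage is expected to remove).
    """
    if spec.bleach_frame_index is None:
        raise ValueError("generate_frap_series requires bleach_frame_index to be set")
    if spec.bleach_frame_index == 0:
        raise ValueError("at least one pre-bleach frame is required")
    if truth.pcm_sigma_um <= spec.psf_sigma_um:
        raise ValueError("pcm_sigma_um must exceed psf_sigma_um (broad matrix signal)")
    ms = np.asarray(microscope_shift_um, dtype=float)
    center = np.asarray(truth.pcm_center_um)
    _check_in_field(center[None], spec, "centrosome")

    rng = np.random.default_rng(spec.rng_seed)
    photons = spec.photons_per_emitter
    focus_sigma = spec.psf_sigma_um
    red_recover_center = center + np.asarray(truth.channel_offset_um) + ms

    prebleach_red = [tuple(np.asarray(truth.mother_pos_um) + ms)]
    if truth.daughter_pos_um is not None:
        prebleach_red.append(tuple(np.asarray(truth.daughter_pos_um) + ms))
    per_focus = photons / len(prebleach_red)

    frames = []
    for i, _t in enumerate(spec.frame_times_s):
        a_green = _recovery_amplitude(
            i, spec, truth.recovery_rate_per_s[0], truth.recovered_fraction[0],
            truth.recovery_delay_frame[0],
        )
        a_red = _recovery_amplitude(
            i, spec, truth.recovery_rate_per_s[1], truth.recovered_fraction[1],
            truth.recovery_delay_frame[1],
        )
        sigma_pcm = _pcm_sigma_at(i, spec, truth)
        green = _render_emitters(
            spec, [(center[0], center[1], photons * a_green, sigma_pcm)]
        )
        if i < spec.bleach_frame_index:
            red_emitters = [(x, y, per_focus, focus_sigma) for x, y in prebleach_red]
        else:
            red_emitters = [
                (red_recover_center[0], red_recover_center[1], photons * a_red, focus_sigma)
            ]
        red = _render_emitters(spec, red_emitters)
        frames.append(np.stack([_apply_noise(green, spec, rng), _apply_noise(red, spec, rng)]))

    series = ImageSeries(
        pixels=np.stack(frames),
        pixel_size_um=spec.pixel_size_um,
        z_spacing_um=spec.z_spacing_um,
        frame_times_s=list(spec.frame_times_s),
        channel_names=["green", "red"],
        bleach_frame_index=spec.bleach_frame_index,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Position-level foci scenes (super-resolution analysis operates on centroids)


def simulate_foci_dataset(
    n: int,
    rng: np.random.Generator,
    mother_distance_range_um: tuple[float, float] = (0.03, 0.12),
    daughter_distance_range_um: tuple[float, float] = (0.18, 0.30),
    localisation_noise_sd_um: float = 0.02,
):
    """Simulate mother/daughter/post-bleach focus positions around a toroid.

    The post-bleach focus is drawn at the daughter position; all observed
    positions carry independent Gaussian localisation noise.  Returns a list
    of dicts with observed positions and true labels for oracle checks.
    """
    records = []
    for _ in range(n):
        center = rng.uniform(2.0, 8.0, size=2)
        theta_m = rng.uniform(0, 2 * np.pi)
        theta_d = rng.uniform(0, 2 * np.pi)
        d_m = rng.uniform(*mother_distance_range_um)
        d_d = rng.uniform(*daughter_distance_range_um)
        mother = center + d_m * np.array([np.cos(theta_m), np.sin(theta_m)])
        daughter = center + d_d * np.array([np.cos(theta_d), np.sin(theta_d)])
        post = daughter.copy()

        def obs(p):
            return tuple(p + rng.normal(0.0, localisation_noise_sd_um, size=2))

        foci = [obs(mother), obs(daughter)]
        order = rng.permutation(2)  # observed foci arrive unlabeled
        records.append(
            {
                "toroid_center_um": tuple(center),
                "prebleach_foci_um": [foci[order[0]], foci[order[1]]],
                "postbleach_focus_um": obs(post),
                "true_mother_index": int(np.flatnonzero(order == 0)[0]),
            }
        )
    return records


# ---------------------------------------------------------------------------
# Truth serialisation


def _truth_to_dict(truth) -> dict:
    d = asdict(truth)
    d["__type__"] = type(truth).__name__
    return d


def save_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_truth_to_dict(truth), fh, indent=1)
    return path


def load_truth(path: str | Path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.pop("__type__")
    def _pair(v):
        return None if v is None else tuple(v)
    if kind == "BeadFieldTruth":
        return BeadFieldTruth(
            bead_positions_um=tuple(tuple(p) for p in d["bead_positions_um"]),
            true_shift_um=tuple(d["true_shift_um"]),
            per_bead_jitter_sd_um=d["per_bead_jitter_sd_um"],
        )
    if kind == "CentrosomeTruth":
        return CentrosomeTruth(
            pcm_center_um=tuple(d["pcm_center_um"]),
            mother_pos_um=tuple(d["mother_pos_um"]),
            daughter_pos_um=_pair(d["daughter_pos_um"]),
            pcm_sigma_um=d["pcm_sigma_um"],
            channel_offset_um=tuple(d["channel_offset_um"]),
            recovery_rate_per_s=tuple(d["recovery_rate_per_s"]),
            recovered_fraction=tuple(d["recovered_fraction"]),
            recovery_delay_frame=tuple(d["recovery_delay_frame"]),
            pcm_sigma_end_um=d["pcm_sigma_end_um"],
        )
    raise ValueError(f"unknown truth type {kind!r}")
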