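"""Channel registration from fiducial bead fields.

Estimates the systematic red-minus-green displacement as the mean of
per-bead displacement vectors pooled over all calibration images, and
applies it as a pure translation to red-channel coordinates.  A single
translation is deliberate: no affine or field-dependent distortion model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "RegistrationModel",
    "BeadMatches",
    "detect_beads",
    "match_beads",
    "estimate_channel_shift",
    "apply_registration",
]


@dataclass(frozen=True)
class RegistrationModel:
    """Mean red-minus-green shift with its uncertainty.

    ``se_um`` is the standard error of the per-bead displacement magnitudes
    (NaN when only one bead was available); ``sd_um`` their standard
    deviation.
    """

    shift_um: tuple[float, float]
    shift_magnitude_um: float
    se_um: float
    sd_um: float
    n_beads: int
    n_images: int

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        mag = float(np.hypot(*self.shift_um))
        if not np.isclose(mag, self.shift_magnitude_um, atol=1e-9):
            raise ValueError("shift_magnitude_um inconsistent with shift_um")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "shift_um": list(self.shift_um),
            "shift_magnitude_um": self.shift_magnitude_um,
            "se_um": None if np.isnan(self.se_um) else self.se_um,
            "sd_um": None if np.isnan(self.sd_um) else self.sd_um,
            "n_beads": self.n_beads,
            "n_images": self.n_images,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            shift_um=tuple(d["shift_um"]),
            shift_magnitude_um=d["shift_magnitude_um"],
            se_um=float("nan") if d["se_um"] is None else d["se_um"],
            sd_um=float("nan") if d["sd_um"] is None else d["sd_um"],
            n_beads=d["n_beads"],
            n_images=d["n_images"],
        )


@dataclass(frozen=True)
class BeadMatches:
    """Mutually-nearest bead pairs from one image pair, positions in um."""

    green_um: np.ndarray  # (M, 2)
    red_um: np.ndarray  # (M, 2)
    n_unmatched_green: int
    n_unmatched_red: int

    @property
    def displacements_um(self) -> np.ndarray:
        return self.red_um - self.green_um


def detect_beads(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    threshold_abs: float | None = None,
    k_sd: float = 4.0,
    min_distance_px: int = 3,
    merge_radius_um: float = 0.4,
    window_radius_px: int = 4,
) -> np.ndarray:
    """Detect sub-resolution spots and refine them to sub-pixel positions.

    Local maxima above ``mean + k_sd * sd`` (or an explicit absolute
    threshold) are refined by a background-subtracted intensity-weighted
    centroid in a ``(2 * window_radius_px + 1)`` square window; the
    background estimate is the median of the window border.  Detections
    closer than ``merge_radius_um`` to another detection are ambiguous and
    are all dropped.  Returns an ``(N, 2)`` array of ``(x, y)`` in um.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_beads expects a single-channel 2-D image")
    if threshold_abs is None:
        threshold_abs = image.mean() + k_sd * image.std()
    peaks = peak_local_max(
        image,
        min_distance=min_distance_px,
        threshold_abs=threshold_abs,
        exclude_border=window_radius_px,
    )
    positions = []
    for r0, c0 in peaks:
        win = image[
            r0 - window_radius_px : r0 + window_radius_px + 1,
            c0 - window_radius_px : c0 + window_radius_px + 1,
        ]
        border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        w = np.clip(win - np.median(border), 0.0, None)
        total = w.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
        dr = (w * rr).sum() / total - window_radius_px
        dc = (w * cc).sum() / total - window_radius_px
        positions.append(((c0 + dc) * pixel_size_um, (r0 + dr) * pixel_size_um))
    if not positions:
        return np.empty((0, 2))
    pos = np.asarray(positions)
    if len(pos) > 1 and merge_radius_um > 0:
        tree = cKDTree(pos)
        close = tree.query_pairs(merge_radius_um)
        drop = {i for pair in close for i in pair}
        if drop:
            pos = pos[[i for i in range(len(pos)) if i not in drop]]
    return pos


def match_beads(
    green_positions: np.ndarray,
    red_positions: np.ndarray,
    max_radius_um: float = 0.3,
) -> BeadMatches:
    """Pair detections by mutual nearest neighbour within ``max_radius_um``."""
    if max_radius_um <= 0:
        raise ValueError("max_radius_um must be positive")
    g = np.atleast_2d(np.asarray(green_positions, dtype=float))
    r = np.atleast_2d(np.asarray(red_positions, dtype=float))
    if g.size == 0 or r.size == 0:
        return BeadMatches(np.empty((0, 2)), np.empty((0, 2)), g.shape[0] if g.size else 0,
                           r.shape[0] if r.size else 0)
    gtree, rtree = cKDTree(g), cKDTree(r)
    d_gr, nn_gr = rtree.query(g, distance_upper_bound=max_radius_um)
    d_rg, nn_rg = gtree.query(r, distance_upper_bound=max_radius_um)
    pairs = [
        (i, int(nn_gr[i]))
        for i in range(len(g))
        if np.isfinite(d_gr[i]) and int(nn_rg[int(nn_gr[i])]) == i
    ]
    if not pairs:
        return BeadMatches(np.empty((0, 2)), np.empty((0, 2)), len(g), len(r))
    gi, ri = zip(*pairs)
    return BeadMatches(
        green_um=g[list(gi)],
        red_um=r[list(ri)],
        n_unmatched_green=len(g) - len(pairs),
        n_unmatched_red=len(r) - len(pairs),
    )


def estimate_channel_shift(matches: list[BeadMatches]) -> RegistrationModel:
    """Pool matched pairs from one or more images into a registration model.

    The shift is the mean displacement VECTOR (a scalar mean of distances
    cannot correct direction); beads from all images are pooled with equal
    weight.
    """
    if not matches:
        raise ValueError("estimate_channel_shift requires at least one image")
    disp = np.concatenate([m.displacements_um for m in matches], axis=0)
    if disp.shape[0] == 0:
        raise ValueError("no matched bead pairs to estimate a shift from")
    shift = disp.mean(axis=0)
    mags = np.hypot(disp[:, 0], disp[:, 1])
    if len(mags) > 1:
        sd = float(np.std(mags, ddof=1))
        se = sd / np.sqrt(len(mags))
    else:
        sd = float("nan")
        se = float("nan")
    return RegistrationModel(
        shift_um=(float(shift[0]), float(shift[1])),
        shift_magnitude_um=float(np.hypot(shift[0], shift[1])),
        se_um=se,
        sd_um=sd,
        n_beads=int(disp.shape[0]),
        n_images=len(matches),
    )


def apply_registration(position_red_um, model: RegistrationModel) -> np.ndarray:
    """Correct a red-channel position: subtract the systematic shift."""
    return np.asarray(position_red_um, dtype=float) - np.asarray(model.shift_um)
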