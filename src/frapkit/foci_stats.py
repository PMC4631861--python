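"""Mother/daughter focus assignment and distance-group statistics.

Given two pre-bleach foci and a reference ("toroid") centre, the focus
nearer the centre is the mother and the farther one the daughter; the
post-bleach recovered focus is then compared to both by distance.  Group
comparisons report box-plot summaries and pairwise two-sided tests
(Mann-Whitney U by default; Welch's t and a permutation test available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .registration import RegistrationModel, apply_registration

__all__ = [
    "UnresolvedPairError",
    "FociAssignment",
    "GroupComparison",
    "assign_foci",
    "compare_distance_groups",
]


class UnresolvedPairError(ValueError):
    pass


@dataclass(frozen=True)
class FociAssignment:
    toroid_center_um: tuple[float, float]
    mother_focus_um: tuple[float, float]
    daughter_focus_um: tuple[float, float]
    postbleach_focus_um: tuple[float, float] | None
    d_mother_um: float
    d_daughter_um: float
    d_postbleach_um: float | None
    ambiguous: bool
    mother_index: int  # index into the input pre-bleach pair


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, ...]
    stats: dict  # label -> {n, mean, median, q25, q75, min, max}
    p_values: dict  # "a_vs_b" -> float (NaN when skipped)
    test_name: str
    notices: tuple[str, ...] = ()


def _dist(a, b) -> float:
    return float(np.hypot(*(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))))


def assign_foci(
    prebleach_foci,
    postbleach_focus,
    toroid_center,
    *,
    model: RegistrationModel | None = None,
    noise_floor_um: float = 0.02,
) -> FociAssignment:
    """Label the pre-bleach foci mother/daughter by distance to the toroid.

    The toroid centre comes from the red channel, so the registration
    correction (if a model is given) is applied to it before distances are
    computed.  A distance difference below ``noise_floor_um`` is flagged
    ambiguous.  Assignment is invariant to the input order of the two foci.
    """
    foci = [np.asarray(f, dtype=float) for f in prebleach_foci]
    if len(foci) != 2:
        raise UnresolvedPairError(
            f"exactly two pre-bleach foci are required; got {len(foci)} (unresolved pair)"
        )
    center = np.asarray(toroid_center, dtype=float)
    if model is not None:
        center = apply_registration(center, model)
    d = [_dist(f, center) for f in foci]
    mother_idx = int(np.argmin(d))
    daughter_idx = 1 - mother_idx
    post = None if postbleach_focus is None else np.asarray(postbleach_focus, dtype=float)
    return FociAssignment(
        toroid_center_um=tuple(center),
        mother_focus_um=tuple(foci[mother_idx]),
        daughter_focus_um=tuple(foci[daughter_idx]),
        postbleach_focus_um=None if post is None else tuple(post),
        d_mother_um=d[mother_idx],
        d_daughter_um=d[daughter_idx],
        d_postbleach_um=None if post is None else _dist(post, center),
        ambiguous=abs(d[0] - d[1]) < noise_floor_um,
        mother_index=mother_idx,
    )


def _box_stats(values: np.ndarray) -> dict:
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def _permutation_p(a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
                   n_permutations: int) -> float:
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def compare_distance_groups(
    d_mother,
    d_daughter,
    d_postbleach,
    *,
    test: str = "mannwhitney",
    n_permutations: int = 9999,
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Box-plot summaries plus pairwise two-sided tests of the post-bleach group.

    Tested pairs: postbleach vs mother and postbleach vs daughter.  A group
    whose values are all equal is degenerate; its tests are skipped
    (p = NaN) with a notice.  ``test`` is one of ``mannwhitney`` (default),
    ``welch`` or ``permutation``.
    """
    groups = {
        "mother": np.asarray(d_mother, dtype=float),
        "daughter": np.asarray(d_daughter, dtype=float),
        "postbleach": np.asarray(d_postbleach, dtype=float),
    }
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs n >= 2; got {len(vals)}")
    if test not in ("mannwhitney", "welch", "permutation"):
        raise ValueError(f"unknown test {test!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    notices: list[str] = []
    p_values: dict[str, float] = {}
    for other in ("mother", "daughter"):
        key = f"postbleach_vs_{other}"
        a, b = groups["postbleach"], groups[other]
        degenerate = [
            lbl for lbl, v in (("postbleach", a), (other, b)) if np.ptp(v) == 0
        ]
        if degenerate:
            p_values[key] = float("nan")
            notices.append(
                f"{key}: skipped, degenerate all-equal group(s): {', '.join(degenerate)}"
            )
            continue
        if test == "mannwhitney":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            p = _permutation_p(a, b, rng, n_permutations)
        p_values[key] = float(p)

    return GroupComparison(
        group_labels=tuple(groups),
        stats={label: _box_stats(vals) for label, vals in groups.items()},
        p_values=p_values,
        test_name=test,
        notices=tuple(notices),
    )
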