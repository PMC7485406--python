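"""Feature-pair points baseline model of transition costs.

An ordinal baseline against which the episodic simulator is compared: for
each trial transition the four features cue, task, stimulus and response
(the decision is deliberately not a feature) are marked repeated or not,
and every one of the 6 unordered feature pairs contributes -1 point when
both members repeat, +1 when exactly one repeats, and 0 when neither does.
Conditions with fewer net points are predicted to be faster.  For
comparison with observed response times the points are linearly rescaled
("stretched") to the standard deviation of the reference condition means
and centered on their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "TransitionFlags",
    "PointsBreakdown",
    "altmann_points",
    "condition_flags",
    "condition_points",
    "rescale_predictions",
]

_FEATURES = ("cue", "task", "stimulus", "response")


@dataclass(frozen=True)
class TransitionFlags:
    """Which of the four features repeat from the previous trial."""

    cue_repeats: bool
    task_repeats: bool
    stimulus_repeats: bool
    response_repeats: bool

    def __post_init__(self) -> None:
        if self.cue_repeats and not self.task_repeats:
            raise ValueError("a repeated cue implies a repeated task")


@dataclass(frozen=True)
class PointsBreakdown:
    positive: int
    negative: int

    @property
    def net(self) -> int:
        return self.positive - self.negative


def altmann_points(flags: TransitionFlags) -> PointsBreakdown:
    """Score the 6 unordered feature pairs of a transition."""
    reps = (
        flags.cue_repeats,
        flags.task_repeats,
        flags.stimulus_repeats,
        flags.response_repeats,
    )
    pos = neg = 0
    for i, j in combinations(range(4), 2):
        if reps[i] and reps[j]:
            neg += 1
        elif reps[i] or reps[j]:
            pos += 1
    return PointsBreakdown(positive=pos, negative=neg)


def condition_flags(condition: str) -> TransitionFlags:
    """Transition flags implied by a ten-way condition label."""
    prefix, sr = condition.split("-")
    task_rep = prefix in ("cue", "rep")
    return TransitionFlags(
        cue_repeats=prefix == "cue",
        task_repeats=task_rep,
        stimulus_repeats=sr[0] == "R",
        response_repeats=sr[1] == "R",
    )


def condition_points(conditions) -> dict[str, PointsBreakdown]:
    return {c: altmann_points(condition_flags(c)) for c in conditions}


def rescale_predictions(
    points_by_condition: dict[str, int | float],
    reference_means: dict[str, float],
) -> dict[str, float]:
    """Affine map of net points onto the reference RT scale.

    Predictions get the same mean and between-condition standard deviation
    as the reference condition means; rank order by points is preserved.
    Degenerate (constant) points cannot be stretched and raise.
    """
    conds = list(points_by_condition)
    missing = set(conds) - set(reference_means)
    if missing:
        raise KeyError(f"reference means missing conditions: {sorted(missing)}")
    pts = np.array([float(points_by_condition[c]) for c in conds])
    ref = np.array([float(reference_means[c]) for c in conds])
    sd_pts = pts.std()
    if sd_pts == 0.0:
        raise ValueError("constant points across conditions cannot be rescaled")
    scaled = ref.mean() + (pts - pts.mean()) * (ref.std() / sd_pts)
    return dict(zip(conds, scaled.tolist()))
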