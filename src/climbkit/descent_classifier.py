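"""Descent segmentation and drop vs descending-climb classification.

Descents are runs of downward movements; internal pauses up to
``max_internal_pause_s`` seconds are absorbed (a controlled walk-down below
6 mm/s at 3 mm resolution necessarily shows zero-delta seconds between
steps, so pause-free segmentation would shatter slow descents into
below-threshold fragments). Velocity is total distance over total duration,
duration spanning the first to last downward movement inclusive of internal
pauses; a fall completed between two samples is attributed the 1 s
resolution floor.

Classification uses strict thresholds: descents must exceed the minimum
recordable distance (> 3 mm); a velocity above 8.97 mm/s is a drop and one
below 6 mm/s is a descending climb; velocities in between cannot be
differentiated and are excluded from both counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .monitor_io import Trajectory

__all__ = [
    "ClassifierParams",
    "Descent",
    "DescentLabel",
    "classify_descent",
    "classify_descents",
    "descent_summary",
    "descent_table",
    "percent_correct",
    "segment_descents",
]


class DescentLabel(str, Enum):
    DROP = "drop"
    DESCENDING_CLIMB = "descending_climb"
    UNCLASSIFIED = "unclassified"
    BELOW_MIN_DISTANCE = "below_min_distance"


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds for descent segmentation and classification.

    All velocity/distance comparisons are strict inequalities.
    """

    min_descent_distance_mm: float = 3.0
    drop_velocity_min_mm_s: float = 8.97
    descclimb_velocity_max_mm_s: float = 6.0
    max_internal_pause_s: int = 2

    def __post_init__(self) -> None:
        if self.descclimb_velocity_max_mm_s >= self.drop_velocity_min_mm_s:
            raise ValueError(
                "descending-climb velocity ceiling must lie below the drop "
                "velocity floor"
            )
        if self.min_descent_distance_mm <= 0:
            raise ValueError("min_descent_distance_mm must be positive")
        if self.max_internal_pause_s < 0:
            raise ValueError("max_internal_pause_s must be >= 0")


@dataclass(frozen=True)
class Descent:
    """One segmented descent episode."""

    start_t_s: int
    end_t_s: int
    distance_mm: float
    label: DescentLabel | None = None

    @property
    def duration_s(self) -> int:
        return self.end_t_s - self.start_t_s

    @property
    def velocity_mm_s(self) -> float:
        return self.distance_mm / self.duration_s


def segment_descents(
    traj: Trajectory, params: ClassifierParams | None = None
) -> list[Descent]:
    """Segment a trajectory into (unlabeled) descent episodes.

    A descent opens at the first downward movement after non-descent,
    accumulates downward movements across internal pauses of at most
    ``max_internal_pause_s`` seconds, and closes at an upward movement, a
    longer pause, or the end of the recording. Trailing pauses are not part
    of the descent.
    """
    params = params or ClassifierParams()
    h = np.asarray(traj.heights_mm, dtype=float)
    descents: list[Descent] = []
    start_t = end_t = -1
    distance = 0.0
    pause = 0
    open_ = False

    def emit() -> None:
        descents.append(Descent(start_t, end_t, distance))

    for t in range(1, len(h)):
        d = h[t] - h[t - 1]
        if open_:
            if d < 0:
                end_t = t
                distance += -d
                pause = 0
            elif d > 0:
                emit()
                open_ = False
            else:
                pause += 1
                if pause > params.max_internal_pause_s:
                    emit()
                    open_ = False
        elif d < 0:
            open_ = True
            start_t, end_t, distance, pause = t - 1, t, -d, 0
    if open_:
        emit()
    return descents


def classify_descent(d: Descent, params: ClassifierParams | None = None) -> Descent:
    """Return the descent with its label assigned (strict thresholds)."""
    params = params or ClassifierParams()
    if d.distance_mm <= params.min_descent_distance_mm:
        label = DescentLabel.BELOW_MIN_DISTANCE
    elif d.velocity_mm_s > params.drop_velocity_min_mm_s:
        label = DescentLabel.DROP
    elif d.velocity_mm_s < params.descclimb_velocity_max_mm_s:
        label = DescentLabel.DESCENDING_CLIMB
    else:
        label = DescentLabel.UNCLASSIFIED
    return replace(d, label=label)


def classify_descents(
    traj: Trajectory, params: ClassifierParams | None = None
) -> list[Descent]:
    """Segment and classify every descent in a trajectory."""
    params = params or ClassifierParams()
    return [classify_descent(d, params) for d in segment_descents(traj, params)]


def descent_summary(
    trajs: Sequence[Trajectory],
    params: ClassifierParams | None = None,
    include_flagged: bool = False,
) -> pd.DataFrame:
    """Per-fly counts of drops, descending climbs, and unclassified descents."""
    params = params or ClassifierParams()
    rows = []
    for tr in trajs:
        if tr.flagged and not include_flagged:
            continue
        labels = [d.label for d in classify_descents(tr, params)]
        rows.append(
            {
                "fly_id": tr.fly_id,
                "n_drops": labels.count(DescentLabel.DROP),
                "n_descending_climbs": labels.count(DescentLabel.DESCENDING_CLIMB),
                "n_unclassified": labels.count(DescentLabel.UNCLASSIFIED),
                "genotype": tr.genotype,
                "age_days": tr.age_days,
                "dose_ug_per_ml": tr.dose_ug_per_ml,
                "start_day": tr.start_day,
            }
        )
    cols = [
        "fly_id",
        "n_drops",
        "n_descending_climbs",
        "n_unclassified",
        "genotype",
        "age_days",
        "dose_ug_per_ml",
        "start_day",
    ]
    return pd.DataFrame(rows, columns=cols)


def descent_table(
    trajs: Sequence[Trajectory],
    params: ClassifierParams | None = None,
    include_flagged: bool = False,
) -> pd.DataFrame:
    """Long table of every classified descent across flies."""
    params = params or ClassifierParams()
    rows = []
    for tr in trajs:
        if tr.flagged and not include_flagged:
            continue
        for d in classify_descents(tr, params):
            rows.append(
                {
                    "fly_id": tr.fly_id,
                    "start_t_s": d.start_t_s,
                    "end_t_s": d.end_t_s,
                    "distance_mm": d.distance_mm,
                    "duration_s": d.duration_s,
                    "velocity_mm_s": d.velocity_mm_s,
                    "label": d.label.value,
                }
            )
    cols = [
        "fly_id",
        "start_t_s",
        "end_t_s",
        "distance_mm",
        "duration_s",
        "velocity_mm_s",
        "label",
    ]
    return pd.DataFrame(rows, columns=cols)


def percent_correct(n_correct: int, n_total: int, ndigits: int = 1) -> float:
    """Classification accuracy as a percentage rounded to ``ndigits``."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_correct / n_total, ndigits)
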