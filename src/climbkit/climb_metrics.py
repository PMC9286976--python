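"""Climbing-event segmentation and the per-fly climbing metric vector.

A climbing event opens at a local minimum preceding an upward movement and
closes when travel reverses from climbing up to climbing down; pauses
between upward movements do not close an event. An ascent still open at the
end of the recording is counted as an event by default (``count_terminal_
ascent``), so a fly that climbs to the top and stays there registers the
climb; the strict reversal-only reading is available by turning the flag
off.

Metrics whose defining set is empty for a fly (e.g. average height climbed
for a motionless fly) are reported as NaN, never zero, so group averages
are not biased downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    AssayGeometry,
    Direction,
    Section,
    dwell_times,
    extract_movements,
)
from .monitor_io import Trajectory

__all__ = [
    "METRIC_COLUMNS",
    "ClimbEvent",
    "ClosedBy",
    "MetricsRecord",
    "compute_metrics",
    "count_complete_ascents",
    "metrics_table",
    "segment_climbs",
]


class ClosedBy(str, Enum):
    REVERSAL = "reversal"
    END_OF_RECORDING = "end_of_recording"


@dataclass(frozen=True)
class ClimbEvent:
    """One climbing episode: local minimum up to the peak before reversal."""

    start_t_s: int
    peak_t_s: int
    start_h_mm: float
    peak_h_mm: float
    reached_top: bool
    closed_by: ClosedBy

    @property
    def height_gained_mm(self) -> float:
        return self.peak_h_mm - self.start_h_mm


@dataclass(frozen=True)
class MetricsRecord:
    """Per-fly vector of climbing metrics; the unit of all group statistics."""

    fly_id: str
    n_climb_events: int
    n_climbs_to_top: int
    avg_height_per_climb_mm: float
    total_height_climbed_mm: float
    avg_peak_height_mm: float
    n_complete_ascents: int
    dwell_lower_s: int
    dwell_middle_s: int
    dwell_top_s: int
    n_movements: int
    ascending_velocity_mm_s: float
    descending_velocity_mm_s: float


METRIC_COLUMNS = [
    "fly_id",
    "n_climb_events",
    "n_climbs_to_top",
    "avg_height_per_climb_mm",
    "total_height_climbed_mm",
    "avg_peak_height_mm",
    "n_complete_ascents",
    "dwell_lower_s",
    "dwell_middle_s",
    "dwell_top_s",
    "n_movements",
    "ascending_velocity_mm_s",
    "descending_velocity_mm_s",
]


def segment_climbs(
    traj: Trajectory,
    count_terminal_ascent: bool = True,
    geom: AssayGeometry | None = None,
) -> list[ClimbEvent]:
    """Segment a trajectory into climbing events (see module docstring)."""
    geom = geom or AssayGeometry()
    h = np.asarray(traj.heights_mm, dtype=float)
    events: list[ClimbEvent] = []
    start: tuple[int, float] | None = None  # (t, h) of the opening minimum
    peak: tuple[int, float] | None = None

    def close(by: ClosedBy) -> None:
        assert start is not None and peak is not None
        events.append(
            ClimbEvent(
                start_t_s=start[0],
                peak_t_s=peak[0],
                start_h_mm=start[1],
                peak_h_mm=peak[1],
                reached_top=peak[1] == geom.tube_length_mm,
                closed_by=by,
            )
        )

    for t in range(1, len(h)):
        d = h[t] - h[t - 1]
        if d > 0:
            if start is None:
                start = (t - 1, float(h[t - 1]))
            peak = (t, float(h[t]))
        elif d < 0 and start is not None:
            close(ClosedBy.REVERSAL)
            start = peak = None
        # d == 0: pause, leaves any open event open
    if start is not None and count_terminal_ascent:
        close(ClosedBy.END_OF_RECORDING)
    return events


def count_complete_ascents(
    traj: Trajectory, geom: AssayGeometry | None = None
) -> int:
    """Count bottom-to-top ascents with no intervening downward movement.

    A qualifying run starts at the lowest recordable height (one increment,
    the lowest observable state above the tube plug), may pause, and must
    reach the full tube length before any downward movement.
    """
    geom = geom or AssayGeometry()
    h = np.asarray(traj.heights_mm, dtype=float)
    bottom = geom.increment_mm
    top = geom.tube_length_mm
    count = 0
    in_run = False
    for t in range(1, len(h)):
        d = h[t] - h[t - 1]
        if d > 0:
            if not in_run and h[t - 1] == bottom:
                in_run = True
            if in_run and h[t] == top:
                count += 1
                in_run = False
        elif d < 0:
            in_run = False
    return count


def _mean_or_nan(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else math.nan


def compute_metrics(
    traj: Trajectory,
    geom: AssayGeometry | None = None,
    count_terminal_ascent: bool = True,
) -> MetricsRecord:
    """Compute the full per-fly climbing metric vector.

    - total height climbed sums every positive per-second delta over the
      whole assay, whether or not the second belongs to a closed event;
    - ascending/descending velocity is the mean per-second displacement over
      seconds with a movement in that direction (the native estimate at
      1 Hz / one-increment resolution), NaN when no such second exists.
    """
    geom = geom or AssayGeometry()
    events = segment_climbs(traj, count_terminal_ascent, geom)
    movements = extract_movements(traj)
    dwell = dwell_times(traj, geom)

    up = [m.delta_h_mm for m in movements if m.direction is Direction.UP]
    down = [-m.delta_h_mm for m in movements if m.direction is Direction.DOWN]

    return MetricsRecord(
        fly_id=traj.fly_id,
        n_climb_events=len(events),
        n_climbs_to_top=sum(e.reached_top for e in events),
        avg_height_per_climb_mm=_mean_or_nan([e.height_gained_mm for e in events]),
        total_height_climbed_mm=float(sum(up)),
        avg_peak_height_mm=_mean_or_nan([e.peak_h_mm for e in events]),
        n_complete_ascents=count_complete_ascents(traj, geom),
        dwell_lower_s=dwell[Section.LOWER],
        dwell_middle_s=dwell[Section.MIDDLE],
        dwell_top_s=dwell[Section.TOP],
        n_movements=len(movements),
        ascending_velocity_mm_s=_mean_or_nan(up),
        descending_velocity_mm_s=_mean_or_nan(down),
    )


def metrics_table(
    trajs: Sequence[Trajectory],
    geom: AssayGeometry | None = None,
    count_terminal_ascent: bool = True,
    include_flagged: bool = False,
) -> pd.DataFrame:
    """One MetricsRecord row per fly, carrying group metadata columns.

    Flies flagged by the gap policy are excluded unless ``include_flagged``.
    """
    rows = []
    for tr in trajs:
        if tr.flagged and not include_flagged:
            continue
        rec = compute_metrics(tr, geom, count_terminal_ascent)
        row = {c: getattr(rec, c) for c in METRIC_COLUMNS}
        row.update(
            genotype=tr.genotype,
            age_days=tr.age_days,
            dose_ug_per_ml=tr.dose_ug_per_ml,
            start_day=tr.start_day,
        )
        rows.append(row)
    cols = METRIC_COLUMNS + ["genotype", "age_days", "dose_ug_per_ml", "start_day"]
    return pd.DataFrame(rows, columns=cols)
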