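"""Synthetic fly trajectories with ground-truth event logs.

A fly is simulated as a continuous-time semi-Markov cycle —
rest-at-bottom, ascend to a drawn peak, rest at the peak, descend (drop or
descending climb) — whose piecewise-linear height path is then sampled at
1 Hz and quantized to the monitor's 3 mm bins, exactly like the real
instrument. The generator also emits the true event sequence so that
segmentation and classification can be scored against known answers.

Presets are calibrated only to the directional group differences the assay
is meant to expose (control climbs higher and performs more descending
climbs; the mutant dwells at the bottom), never to measured group means.
Default presets keep true descent speeds well clear of the classifier's
undifferentiable velocity band: drops are near-instantaneous and
descending climbs stay in the 1–4.5 mm/s range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descent_classifier import ClassifierParams, DescentLabel, classify_descents
from .kinematics import AssayGeometry
from .monitor_io import FlightRecord, Trajectory

__all__ = [
    "PRESETS",
    "EventType",
    "GroundTruthEvent",
    "GroundTruthLog",
    "PhenotypePreset",
    "classification_accuracy",
    "get_preset",
    "ground_truth_frame",
    "match_descents_to_truth",
    "simulate_cohort",
    "simulate_flight",
    "simulate_flight_window",
    "simulate_fly",
]


class EventType(str, Enum):
    ASCENT = "ascent"
    DROP = "drop"
    DESCENDING_CLIMB = "descending_climb"
    REST = "rest"


@dataclass(frozen=True)
class GroundTruthEvent:
    """One true behavioral episode on the continuous timeline."""

    type: EventType
    t_start: float
    t_end: float
    h_start: float
    h_end: float
    true_velocity: float  # mm/s, 0 for rests


@dataclass
class GroundTruthLog:
    """True event sequence for one simulated fly; events tile the timeline."""

    fly_id: str
    events: list[GroundTruthEvent] = field(default_factory=list)

    def count(self, type_: EventType) -> int:
        return sum(e.type is type_ for e in self.events)


@dataclass(frozen=True)
class PhenotypePreset:
    """Behavioral parameters for one simulated phenotype group."""

    name: str
    genotype: str
    dose_ug_per_ml: float
    climb_initiation_rate_per_min: float
    ascent_speed_mean_mm_s: float
    ascent_speed_sd_mm_s: float
    peak_height_weights: dict[float, float]  # height -> relative weight
    prob_descent_is_drop: float
    descclimb_speed_range_mm_s: tuple[float, float]
    drop_speed_mm_s: float = 100.0
    peak_rest_mean_s: float = 6.0
    bottom_bias: float = 0.85
    rest_floor_s: float = 1.0

    def __post_init__(self) -> None:
        for p, label in [
            (self.prob_descent_is_drop, "prob_descent_is_drop"),
            (self.bottom_bias, "bottom_bias"),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        if self.climb_initiation_rate_per_min < 0:
            raise ValueError("climb_initiation_rate_per_min must be >= 0")
        if self.ascent_speed_mean_mm_s <= 0 or self.drop_speed_mm_s <= 0:
            raise ValueError("speeds must be positive")
        lo, hi = self.descclimb_speed_range_mm_s
        if not (0 < lo <= hi):
            raise ValueError("descclimb_speed_range_mm_s must be 0 < lo <= hi")
        if not self.peak_height_weights:
            raise ValueError("peak_height_weights must be non-empty")
        if any(w < 0 for w in self.peak_height_weights.values()):
            raise ValueError("peak height weights must be >= 0")


PRESETS: dict[str, PhenotypePreset] = {
    "control": PhenotypePreset(
        name="control",
        genotype="control",
        dose_ug_per_ml=0.0,
        climb_initiation_rate_per_min=4.0,
        ascent_speed_mean_mm_s=8.0,
        ascent_speed_sd_mm_s=2.0,
        peak_height_weights={21.0: 0.10, 30.0: 0.15, 39.0: 0.20, 51.0: 0.55},
        prob_descent_is_drop=0.35,
        descclimb_speed_range_mm_s=(1.0, 4.5),
        peak_rest_mean_s=8.0,
        bottom_bias=0.80,
    ),
    "park25": PhenotypePreset(
        name="park25",
        genotype="park25",
        dose_ug_per_ml=0.0,
        climb_initiation_rate_per_min=2.5,
        ascent_speed_mean_mm_s=7.0,
        ascent_speed_sd_mm_s=2.0,
        peak_height_weights={12.0: 0.30, 21.0: 0.35, 30.0: 0.20, 39.0: 0.10, 51.0: 0.05},
        prob_descent_is_drop=0.60,
        descclimb_speed_range_mm_s=(1.0, 4.5),
        peak_rest_mean_s=4.0,
        bottom_bias=0.90,
    ),
    "control_nicotine": PhenotypePreset(
        name="control_nicotine",
        genotype="control",
        dose_ug_per_ml=9.0,
        climb_initiation_rate_per_min=3.5,
        ascent_speed_mean_mm_s=8.0,
        ascent_speed_sd_mm_s=2.0,
        peak_height_weights={21.0: 0.15, 30.0: 0.20, 39.0: 0.25, 51.0: 0.40},
        prob_descent_is_drop=0.50,
        descclimb_speed_range_mm_s=(1.0, 4.5),
        peak_rest_mean_s=7.0,
        bottom_bias=0.82,
    ),
    "park25_nicotine": PhenotypePreset(
        name="park25_nicotine",
        genotype="park25",
        dose_ug_per_ml=9.0,
        climb_initiation_rate_per_min=3.5,
        ascent_speed_mean_mm_s=7.5,
        ascent_speed_sd_mm_s=2.0,
        peak_height_weights={21.0: 0.20, 30.0: 0.20, 39.0: 0.25, 51.0: 0.35},
        prob_descent_is_drop=0.40,
        descclimb_speed_range_mm_s=(1.0, 4.5),
        peak_rest_mean_s=6.0,
        bottom_bias=0.85,
    ),
}


def get_preset(name: str) -> PhenotypePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


_ASCENT_SPEED_MIN = 3.0  # quantization-safe regime for event recovery
_ASCENT_SPEED_MAX = 12.0


def _rest(rng: np.random.Generator, mean_s: float, floor_s: float) -> float:
    return floor_s + rng.exponential(max(mean_s - floor_s, 1e-9))


def simulate_fly(
    preset: PhenotypePreset,
    duration_s: int = 1200,
    seed: int | np.random.SeedSequence = 0,
    *,
    fly_id: str = "sim",
    geom: AssayGeometry | None = None,
    genotype: str | None = None,
    dose_ug_per_ml: float | None = None,
    age_days: int = 20,
    start_day: int | None = None,
) -> tuple[Trajectory, GroundTruthLog]:
    """Simulate one fly; returns the quantized trajectory and true event log.

    Identical (preset, duration, seed) always yield identical outputs.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    geom = geom or AssayGeometry()
    rng = np.random.default_rng(seed)
    bottom = geom.increment_mm
    top = geom.tube_length_mm
    peaks = np.array(sorted(preset.peak_height_weights))
    weights = np.array([preset.peak_height_weights[p] for p in peaks], dtype=float)

    events: list[GroundTruthEvent] = []
    t, h = 0.0, bottom
    phase = "rest_bottom"

    def push(type_: EventType, dur: float, h_end: float, speed: float) -> float:
        """Append an event, clipping at the assay end; returns new height."""
        nonlocal t
        t_end = t + dur
        if t_end > duration_s:
            frac = (duration_s - t) / dur if dur > 0 else 0.0
            h_end = h + frac * (h_end - h)
            t_end = float(duration_s)
        events.append(GroundTruthEvent(type_, t, t_end, h, h_end, speed))
        t = t_end
        return h_end

    while t < duration_s:
        if phase == "rest_bottom":
            if preset.climb_initiation_rate_per_min == 0:
                h = push(EventType.REST, duration_s - t, h, 0.0)
                break
            mean = 60.0 / preset.climb_initiation_rate_per_min
            h = push(EventType.REST, _rest(rng, mean, preset.rest_floor_s), h, 0.0)
            phase = "ascent"
        elif phase == "ascent":
            mask = peaks > h
            if not mask.any():
                phase = "descent"
                continue
            w = weights[mask]
            target = float(rng.choice(peaks[mask], p=w / w.sum()))
            speed = float(
                np.clip(
                    rng.normal(preset.ascent_speed_mean_mm_s, preset.ascent_speed_sd_mm_s),
                    _ASCENT_SPEED_MIN,
                    _ASCENT_SPEED_MAX,
                )
            )
            h = push(EventType.ASCENT, (target - h) / speed, target, speed)
            phase = "rest_peak"
        elif phase == "rest_peak":
            h = push(
                EventType.REST,
                _rest(rng, preset.peak_rest_mean_s, preset.rest_floor_s),
                h,
                0.0,
            )
            phase = "descent"
        else:  # descent
            if h <= bottom:
                phase = "rest_bottom"
                continue
            if rng.random() < preset.prob_descent_is_drop:
                type_, target = EventType.DROP, bottom
                speed = preset.drop_speed_mm_s
            else:
                type_ = EventType.DESCENDING_CLIMB
                lo, hi = preset.descclimb_speed_range_mm_s
                speed = float(rng.uniform(lo, hi))
                if rng.random() < preset.bottom_bias:
                    target = bottom
                else:
                    # controlled partial descent onto a lower grid height
                    opts = np.arange(bottom, h - 2 * geom.increment_mm, geom.increment_mm)
                    target = float(rng.choice(opts)) if len(opts) else bottom
            h = push(type_, (h - target) / speed, target, speed)
            phase = "rest_bottom"

    # sample the piecewise-linear path at 1 Hz and quantize to position bins
    xs = [events[0].t_start] + [e.t_end for e in events]
    ys = [events[0].h_start] + [e.h_end for e in events]
    cont = np.interp(np.arange(duration_s), xs, ys)
    positions = np.clip(np.round(cont / geom.increment_mm), 1, geom.n_positions)
    heights = positions * geom.increment_mm

    traj = Trajectory(
        fly_id=fly_id,
        heights_mm=heights,
        genotype=genotype if genotype is not None else preset.genotype,
        age_days=age_days,
        dose_ug_per_ml=(
            dose_ug_per_ml if dose_ug_per_ml is not None else preset.dose_ug_per_ml
        ),
        start_day=start_day,
    )
    return traj, GroundTruthLog(fly_id=fly_id, events=events)


def simulate_cohort(
    design: Mapping[str, tuple[PhenotypePreset | str, int]],
    duration_s: int = 1200,
    seed: int = 0,
    geom: AssayGeometry | None = None,
) -> tuple[list[Trajectory], list[GroundTruthLog]]:
    """Simulate every group in a design.

    ``design`` maps a group name to (preset or preset name, n flies).
    Per-fly seeds are derived from the master seed, the group's rank in
    sorted name order, and the fly index, so cohorts are reproducible
    independent of dict iteration order.
    """
    if len(set(design)) != len(design):
        raise ValueError("duplicate group names in design")
    trajs: list[Trajectory] = []
    logs: list[GroundTruthLog] = []
    for group_rank, group in enumerate(sorted(design)):
        preset, n = design[group]
        if isinstance(preset, str):
            preset = get_preset(preset)
        if n < 1:
            raise ValueError(f"group {group!r}: n must be >= 1, got {n}")
        for i in range(n):
            ss = np.random.SeedSequence([seed, group_rank, i])
            traj, log = simulate_fly(
                preset,
                duration_s,
                ss,
                fly_id=f"{group}_{i:03d}",
                geom=geom,
            )
            trajs.append(traj)
            logs.append(log)
    return trajs, logs


def ground_truth_frame(logs: Sequence[GroundTruthLog]) -> pd.DataFrame:
    """All true events across flies as one long table."""
    rows = [
        {
            "fly_id": log.fly_id,
            "type": e.type.value,
            "t_start": e.t_start,
            "t_end": e.t_end,
            "h_start": e.h_start,
            "h_end": e.h_end,
            "true_velocity": e.true_velocity,
        }
        for log in logs
        for e in log.events
    ]
    cols = ["fly_id", "type", "t_start", "t_end", "h_start", "h_end", "true_velocity"]
    return pd.DataFrame(rows, columns=cols)


def simulate_flight(
    fly_probability: float,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    *,
    genotype: str = "park25",
    dose_ug_per_ml: float = 0.0,
    start_day: int | None = None,
    id_prefix: str = "fly",
) -> list[FlightRecord]:
    """Draw n independent binary flight outcomes at a fixed probability."""
    if not (0.0 <= fly_probability <= 1.0):
        raise ValueError("fly_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    outcomes = rng.random(n) < fly_probability
    return [
        FlightRecord(
            fly_id=f"{id_prefix}_{i:04d}",
            genotype=genotype,
            dose_ug_per_ml=dose_ug_per_ml,
            start_day=start_day,
            flew=bool(o),
        )
        for i, o in enumerate(outcomes)
    ]


def simulate_flight_window(
    day_probabilities: Mapping[int, float],
    baseline_probability: float,
    n_per_group: int,
    seed: int = 0,
    *,
    genotype: str = "park25",
    dose_ug_per_ml: float = 4.5,
) -> list[FlightRecord]:
    """Flight cohort for a delayed-treatment-start design.

    One treated group per start day (flight probability from
    ``day_probabilities``) plus a shared untreated baseline group at
    ``baseline_probability`` (dose 0, no start day).
    """
    records = simulate_flight(
        baseline_probability,
        n_per_group,
        np.random.SeedSequence([seed, 0]),
        genotype=genotype,
        dose_ug_per_ml=0.0,
        start_day=None,
        id_prefix=f"{genotype}_untreated",
    )
    for day in sorted(day_probabilities):
        records.extend(
            simulate_flight(
                day_probabilities[day],
                n_per_group,
                np.random.SeedSequence([seed, 1 + day]),
                genotype=genotype,
                dose_ug_per_ml=dose_ug_per_ml,
                start_day=day,
                id_prefix=f"{genotype}_d{day}",
            )
        )
    return records


def match_descents_to_truth(
    traj: Trajectory,
    log: GroundTruthLog,
    params: ClassifierParams | None = None,
    min_true_distance_mm: float = 6.0,
) -> list[tuple[EventType, DescentLabel | None]]:
    """Pair each true descent with the overlapping segmented descent's label.

    Only true descents at least ``min_true_distance_mm`` tall are evaluated
    (shorter ones are not reliably representable at 3 mm resolution).
    A true descent with no overlapping segmented descent pairs with None.
    """
    params = params or ClassifierParams()
    detected = classify_descents(traj, params)
    pairs: list[tuple[EventType, DescentLabel | None]] = []
    for ev in log.events:
        if ev.type not in (EventType.DROP, EventType.DESCENDING_CLIMB):
            continue
        if ev.h_start - ev.h_end < min_true_distance_mm:
            continue
        best, best_overlap = None, 0.0
        for d in detected:
            # descent spans [start_t, end_t]; pad by the 1 s sampling slack
            overlap = min(d.end_t_s + 0.5, ev.t_end) - max(d.start_t_s - 0.5, ev.t_start)
            if overlap > best_overlap:
                best, best_overlap = d, overlap
        pairs.append((ev.type, best.label if best is not None else None))
    return pairs


def classification_accuracy(
    trajs: Sequence[Trajectory],
    logs: Sequence[GroundTruthLog],
    params: ClassifierParams | None = None,
) -> dict:
    """Score descent classification against ground truth.

    Mirrors a video-validation design: accuracy is computed over true
    descents whose detected counterpart was differentiated as a drop or a
    descending climb; undifferentiated ones are reported separately.
    """
    params = params or ClassifierParams()
    by_id = {log.fly_id: log for log in logs}
    n_correct = n_differentiated = n_true = 0
    for tr in trajs:
        for true_type, label in match_descents_to_truth(tr, by_id[tr.fly_id], params):
            n_true += 1
            if label in (DescentLabel.DROP, DescentLabel.DESCENDING_CLIMB):
                n_differentiated += 1
                n_correct += label.value == true_type.value
    return {
        "n_true_descents": n_true,
        "n_differentiated": n_differentiated,
        "n_correct": n_correct,
        "accuracy_pct": (
            100.0 * n_correct / n_differentiated if n_differentiated else float("nan")
        ),
    }
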