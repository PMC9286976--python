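"""Readers and writers for monitor recordings and canonical tables.

Two on-disk dialects are supported:

``multibeam_tsv``
    A documented reconstruction of a multibeam activity-monitor export
    (long format). Tab-delimited, ``#`` comment lines allowed::

        # t_s   tube    position
        0       1       1
        1       1       2
        2       1       2

    One row per (second, tube); ``position`` is the 1-based beam index
    (1..17 for the default geometry) or empty for a dropped reading.
    Fly metadata comes from an optional YAML manifest mapping tube ids to
    ``fly_id``, ``genotype``, ``age_days``, ``dose_ug_per_ml``, ``start_day``.

``canonical_table``
    The package's lossless long-format trajectory table (TSV) with columns
    ``fly_id, t_s, height_mm, genotype, age_days, dose_ug_per_ml, start_day``.

Gap policy: a missing second inherits the previous position (hold-last);
any gap longer than ``max_gap_s`` (default 5 s) marks the trajectory as
``flagged`` so downstream steps can exclude it audibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import AssayGeometry, position_to_height

__all__ = [
    "GENOTYPES",
    "CANONICAL_COLUMNS",
    "FLIGHT_COLUMNS",
    "FlightRecord",
    "MonitorParseError",
    "MonitorRecord",
    "Trajectory",
    "read_flight_table",
    "read_monitor_file",
    "write_canonical",
    "write_flight_table",
]

GENOTYPES = ("control", "park25")

CANONICAL_COLUMNS = [
    "fly_id",
    "t_s",
    "height_mm",
    "genotype",
    "age_days",
    "dose_ug_per_ml",
    "start_day",
]

FLIGHT_COLUMNS = ["fly_id", "genotype", "dose_ug_per_ml", "start_day", "flew"]

DEFAULT_ASSAY_DURATION_S = 1200  # 20 min at 1 Hz
DEFAULT_MAX_GAP_S = 5

_TRUE_TOKENS = {"1", "yes", "true"}
_FALSE_TOKENS = {"0", "no", "false"}


class MonitorParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class MonitorRecord:
    """One raw monitor reading: a tube's beam position at one second."""

    timestamp: int
    tube_id: int
    position_index: int | None


@dataclass
class Trajectory:
    """One fly's per-second height series plus group metadata.

    ``flagged`` is set by the gap policy when the raw recording contained a
    dropout longer than the tolerated maximum; flagged flies are excluded
    by default downstream but kept available for auditing.
    """

    fly_id: str
    heights_mm: np.ndarray
    genotype: str = "control"
    age_days: int = 20
    dose_ug_per_ml: float = 0.0
    start_day: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype {self.genotype!r} not one of {GENOTYPES}"
            )
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")
        if self.dose_ug_per_ml < 0:
            raise ValueError("dose_ug_per_ml must be >= 0")
        if self.start_day is not None and self.start_day < 0:
            raise ValueError("start_day must be >= 0 or None")

    @property
    def duration_s(self) -> int:
        return len(self.heights_mm)

    def validate_heights(self, geom: AssayGeometry | None = None) -> None:
        """Check every height is a representable bin of the geometry."""
        geom = geom or AssayGeometry()
        valid = set(np.round(geom.heights_mm, 9))
        bad = [h for h in self.heights_mm if round(float(h), 9) not in valid]
        if bad:
            raise ValueError(
                f"trajectory {self.fly_id}: heights {bad[:5]} not on the "
                f"{geom.increment_mm} mm grid 1..{geom.tube_length_mm} mm"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.fly_id == other.fly_id
            and np.array_equal(self.heights_mm, other.heights_mm)
            and self.genotype == other.genotype
            and self.age_days == other.age_days
            and self.dose_ug_per_ml == other.dose_ug_per_ml
            and self.start_day == other.start_day
        )


@dataclass(frozen=True)
class FlightRecord:
    """One fly's binary flight-assay outcome with its group labels."""

    fly_id: str
    genotype: str
    dose_ug_per_ml: float
    start_day: int | None
    flew: bool


def _parse_multibeam(path: Path, geom: AssayGeometry) -> list[MonitorRecord]:
    records: list[MonitorRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MonitorParseError(
                    f"{path}:{lineno}: expected 3 tab-delimited fields "
                    f"(t_s, tube, position), got {len(parts)}"
                )
            try:
                t = int(parts[0])
                tube = int(parts[1])
            except ValueError as exc:
                raise MonitorParseError(f"{path}:{lineno}: {exc}") from exc
            pos: int | None
            if parts[2].strip() == "":
                pos = None
            else:
                try:
                    pos = int(parts[2])
                except ValueError as exc:
                    raise MonitorParseError(f"{path}:{lineno}: {exc}") from exc
                if not (1 <= pos <= geom.n_positions):
                    raise MonitorParseError(
                        f"{path}:{lineno}: position index {pos} outside "
                        f"1..{geom.n_positions}"
                    )
            if not (1 <= tube <= 16):
                raise MonitorParseError(
                    f"{path}:{lineno}: tube id {tube} outside 1..16"
                )
            records.append(MonitorRecord(t, tube, pos))
    return records


def _fill_gaps(
    t: np.ndarray, h: np.ndarray, duration_s: int, max_gap_s: int
) -> tuple[np.ndarray, bool]:
    """Hold-last imputation onto a dense 1 Hz grid; returns (heights, flagged)."""
    heights = np.full(duration_s, np.nan)
    heights[t] = h
    flagged = False
    # leading gap: backfill from first observation
    first = int(np.flatnonzero(~np.isnan(heights))[0])
    if first > 0:
        heights[:first] = heights[first]
        flagged = flagged or first > max_gap_s
    gap = 0
    for i in range(first + 1, duration_s):
        if math.isnan(heights[i]):
            heights[i] = heights[i - 1]
            gap += 1
            if gap > max_gap_s:
                flagged = True
        else:
            gap = 0
    return heights, flagged


def read_monitor_file(
    path: str | Path,
    dialect: str = "multibeam_tsv",
    *,
    geom: AssayGeometry | None = None,
    manifest: str | Path | dict | None = None,
    duration_s: int | None = None,
    max_gap_s: int = DEFAULT_MAX_GAP_S,
) -> list[Trajectory]:
    """Read a recording file and normalize it to one Trajectory per fly.

    Parameters
    ----------
    dialect
        ``"multibeam_tsv"`` (raw monitor export, positions per tube) or
        ``"canonical_table"`` (the package's own trajectory table).
    manifest
        For the multibeam dialect: YAML path or mapping ``tube_id ->
        {fly_id, genotype, age_days, dose_ug_per_ml, start_day}``.
    duration_s
        Expected assay length; defaults to 1200 s for the multibeam dialect
        and to the observed length per fly for canonical tables.
    """
    path = Path(path)
    geom = geom or AssayGeometry()
    if dialect == "canonical_table":
        return _read_canonical(path, geom)
    if dialect != "multibeam_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    records = _parse_multibeam(path, geom)
    if not records:
        return []
    meta: dict[int, dict] = {}
    if manifest is not None:
        if isinstance(manifest, (str, Path)):
            with open(manifest, encoding="utf-8") as fh:
                manifest = yaml.safe_load(fh)
        meta = {int(k): dict(v) for k, v in manifest.items()}

    duration = duration_s if duration_s is not None else DEFAULT_ASSAY_DURATION_S
    trajectories: list[Trajectory] = []
    by_tube: dict[int, list[MonitorRecord]] = {}
    for r in records:
        by_tube.setdefault(r.tube_id, []).append(r)
    for tube in sorted(by_tube):
        rows = by_tube[tube]
        t = np.array([r.timestamp for r in rows])
        if np.any(np.diff(t) <= 0):
            raise MonitorParseError(
                f"{path}: tube {tube}: timestamps not strictly increasing"
            )
        t = t - t[0]  # normalize assay start to t=0
        if t[-1] >= duration:
            raise MonitorParseError(
                f"{path}: tube {tube}: timestamp {t[-1]} beyond assay "
                f"duration {duration}"
            )
        observed = [
            (int(ts), position_to_height(r.position_index, geom))
            for ts, r in zip(t, rows)
            if r.position_index is not None
        ]
        if not observed:
            continue  # empty tube
        ts_arr = np.array([o[0] for o in observed])
        h_arr = np.array([o[1] for o in observed])
        heights, flagged = _fill_gaps(ts_arr, h_arr, duration, max_gap_s)
        m = meta.get(tube, {})
        trajectories.append(
            Trajectory(
                fly_id=str(m.get("fly_id", f"tube{tube:02d}")),
                heights_mm=heights,
                genotype=m.get("genotype", "control"),
                age_days=int(m.get("age_days", 20)),
                dose_ug_per_ml=float(m.get("dose_ug_per_ml", 0.0)),
                start_day=m.get("start_day"),
                flagged=flagged,
            )
        )
    return trajectories


def _read_canonical(path: Path, geom: AssayGeometry) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise MonitorParseError(f"{path}: missing columns {missing}")
    trajectories: list[Trajectory] = []
    for fly_id, sub in df.groupby("fly_id", sort=False):
        sub = sub.sort_values("t_s")
        t = sub["t_s"].to_numpy()
        if np.any(np.diff(t) != 1) or t[0] != 0:
            raise MonitorParseError(
                f"{path}: fly {fly_id}: t_s must be 0,1,2,... with no gaps"
            )
        start_day = sub["start_day"].iloc[0]
        traj = Trajectory(
            fly_id=str(fly_id),
            heights_mm=sub["height_mm"].to_numpy(dtype=float),
            genotype=str(sub["genotype"].iloc[0]),
            age_days=int(sub["age_days"].iloc[0]),
            dose_ug_per_ml=float(sub["dose_ug_per_ml"].iloc[0]),
            start_day=None if pd.isna(start_day) else int(start_day),
        )
        traj.validate_heights(geom)
        trajectories.append(traj)
    return trajectories


def trajectories_to_frame(trajs: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format canonical table for a set of trajectories."""
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "t_s": np.arange(tr.duration_s),
                    "height_mm": tr.heights_mm,
                    "genotype": tr.genotype,
                    "age_days": tr.age_days,
                    "dose_ug_per_ml": tr.dose_ug_per_ml,
                    "start_day": tr.start_day,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CANONICAL_COLUMNS]


def write_canonical(trajs: Sequence[Trajectory], path: str | Path) -> Path:
    """Write trajectories as the canonical TSV table (lossless round trip)."""
    path = Path(path)
    df = trajectories_to_frame(trajs)
    df.to_csv(path, sep="\t", index=False)
    return path


def _parse_flew(token: object, context: str) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise MonitorParseError(
        f"{context}: ambiguous flew value {token!r} "
        f"(expected one of 0/1/yes/no/true/false)"
    )


def read_flight_table(path: str | Path) -> list[FlightRecord]:
    """Read a flight-outcome table (TSV or CSV, sniffed by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FLIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise MonitorParseError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        start_day = row["start_day"]
        records.append(
            FlightRecord(
                fly_id=str(row["fly_id"]),
                genotype=str(row["genotype"]),
                dose_ug_per_ml=float(row["dose_ug_per_ml"]),
                start_day=None if pd.isna(start_day) else int(start_day),
                flew=_parse_flew(row["flew"], f"{path}: row {i + 2}"),
            )
        )
    return records


def write_flight_table(records: Sequence[FlightRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "fly_id": [r.fly_id for r in records],
            "genotype": [r.genotype for r in records],
            "dose_ug_per_ml": [r.dose_ug_per_ml for r in records],
            "start_day": [r.start_day for r in records],
            "flew": [int(r.flew) for r in records],
        },
        columns=FLIGHT_COLUMNS,
    )
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
    return path
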