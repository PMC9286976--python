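"""Tube geometry, position/height conversion, movements, and section dwell times.

The monitor reports a fly's location as a discrete position index along a
vertical tube. All downstream metrics work in millimetres of height, using
the convention ``height = position * increment`` so that the top position
maps exactly to the tube detection length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .monitor_io import Trajectory

__all__ = [
    "AssayGeometry",
    "Direction",
    "Movement",
    "Section",
    "dwell_times",
    "extract_movements",
    "position_to_height",
    "section_of",
]


class Section(str, Enum):
    """Vertical thirds of the climbing tube."""

    LOWER = "lower"
    MIDDLE = "middle"
    TOP = "top"


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class AssayGeometry:
    """Physical layout of the monitored climbing tube.

    Defaults describe a 51 mm detection zone resolved in 3 mm increments
    (17 distinct positions), split into three equal 17 mm sections.
    """

    tube_length_mm: float = 51.0
    increment_mm: float = 3.0
    section_boundaries_mm: tuple[float, float] = (17.0, 34.0)

    def __post_init__(self) -> None:
        if self.tube_length_mm <= 0 or self.increment_mm <= 0:
            raise ValueError("tube_length_mm and increment_mm must be positive")
        n = self.tube_length_mm / self.increment_mm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"tube_length_mm ({self.tube_length_mm}) must be an integer "
                f"multiple of increment_mm ({self.increment_mm})"
            )
        lo, hi = self.section_boundaries_mm
        if not (0 < lo < hi < self.tube_length_mm):
            raise ValueError(
                "section boundaries must be strictly increasing and inside "
                f"(0, {self.tube_length_mm})"
            )

    @property
    def n_positions(self) -> int:
        """Number of distinct position indices along the detection zone."""
        return round(self.tube_length_mm / self.increment_mm)

    @property
    def heights_mm(self) -> np.ndarray:
        """All representable heights, lowest to highest."""
        return self.increment_mm * np.arange(1, self.n_positions + 1)


class Movement(NamedTuple):
    """A nonzero second-to-second positional change.

    ``t_s`` is the timestamp of the sample at which the new position is
    observed; the change occurred between ``t_s - 1`` and ``t_s``.
    """

    t_s: int
    delta_h_mm: float
    direction: Direction


def position_to_height(p: int, geom: AssayGeometry | None = None) -> float:
    """Map a 1-based position index to its height in mm (``h = p * increment``)."""
    geom = geom or AssayGeometry()
    if not (1 <= p <= geom.n_positions):
        raise ValueError(
            f"position index {p} outside valid range 1..{geom.n_positions}"
        )
    return p * geom.increment_mm


def section_of(h: float, geom: AssayGeometry | None = None) -> Section:
    """Assign a height to its tube section (lower / middle / top)."""
    geom = geom or AssayGeometry()
    if not (0 < h <= geom.tube_length_mm):
        raise ValueError(f"height {h} mm outside (0, {geom.tube_length_mm}]")
    lo, hi = geom.section_boundaries_mm
    if h <= lo:
        return Section.LOWER
    if h <= hi:
        return Section.MIDDLE
    return Section.TOP


def extract_movements(traj: "Trajectory") -> list[Movement]:
    """List every second-to-second positional change in a trajectory.

    The number of movements returned is the "total movements" activity
    metric; pauses (equal consecutive heights) contribute nothing.
    """
    h = np.asarray(traj.heights_mm, dtype=float)
    deltas = np.diff(h)
    out: list[Movement] = []
    for i in np.flatnonzero(deltas != 0):
        d = float(deltas[i])
        out.append(
            Movement(int(i + 1), d, Direction.UP if d > 0 else Direction.DOWN)
        )
    return out


def dwell_times(
    traj: "Trajectory", geom: AssayGeometry | None = None
) -> dict[Section, int]:
    """Seconds spent in each tube section.

    Each 1 Hz sample contributes one second to the section of the height
    observed at that sample; the values always sum to the trajectory length.
    """
    geom = geom or AssayGeometry()
    out = {Section.LOWER: 0, Section.MIDDLE: 0, Section.TOP: 0}
    for h in np.asarray(traj.heights_mm, dtype=float):
        out[section_of(float(h), geom)] += 1
    return out
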