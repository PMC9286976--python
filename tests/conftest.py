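from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from climbkit.kinematics import AssayGeometry
from climbkit.monitor_io import Trajectory

HEIGHT_GRID = [3.0 * p for p in range(1, 18)]


def make_traj(heights, fly_id="f1", **meta) -> Trajectory:
    return Trajectory(fly_id=fly_id, heights_mm=np.asarray(heights, dtype=float), **meta)


@pytest.fixture
def geom() -> AssayGeometry:
    return AssayGeometry()


@pytest.fixture
def traj_factory():
    return make_traj


def height_sequences(min_size=2, max_size=60, levels=None):
    """Hypothesis strategy: valid quantized height series."""
    levels = levels if levels is not None else HEIGHT_GRID
    return st.lists(
        st.sampled_from(levels), min_size=min_size, max_size=max_size
    )


def random_walk_heights(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random grid-valued trajectory with mixed steps and pauses."""
    steps = rng.choice([-9, -6, -3, 0, 0, 3, 3, 6, 9], size=n - 1)
    h = np.empty(n)
    h[0] = rng.choice(HEIGHT_GRID)
    for i, s in enumerate(steps):
        h[i + 1] = min(51.0, max(3.0, h[i] + s))
    return h
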