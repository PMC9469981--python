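"""Shared fixtures and helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from hrtb.trajectories import Ensemble, Track


def make_track_1d(xs, dt: float = 3.0, track_id: str = "t") -> Track:
    """Track moving only along x with the given coordinates."""
    xs = np.asarray(xs, dtype=float)
    positions = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    return Track(track_id=track_id, times=np.arange(xs.size) * dt,
                 positions=positions)


def make_track_3d(positions, dt: float = 3.0, track_id: str = "t") -> Track:
    positions = np.asarray(positions, dtype=float)
    return Track(track_id=track_id,
                 times=np.arange(positions.shape[0]) * dt,
                 positions=positions)


@pytest.fixture(scope="session")
def brownian_ensemble():
    """50-track 3D Brownian control (D = 1 um^2/min, 200 frames, 3-min dt)."""
    from hrtb.synthetic import gen_brownian

    ens, _ = gen_brownian(50, 200, frame_dt=3.0, D=1.0, seed=101)
    return ens


@pytest.fixture(scope="session")
def random_walk_tracks():
    """A handful of random-walk tracks for property tests."""
    rng = np.random.default_rng(7)
    tracks = []
    for i in range(5):
        n = int(rng.integers(5, 25))
        steps = rng.normal(0, 2.0, size=(n - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        tracks.append(make_track_3d(pos, track_id=f"rw-{i}"))
    return tracks
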