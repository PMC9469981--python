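"""Heterogeneous run-and-tumble simulator driven by scaled empiricals.

Each simulated walker is tied to one empirical mean triplet (rbar,
thetabar, dtbar) and repeatedly (i) draws a dimensionless sample from each
pooled scaled distribution, (ii) multiplies by its own mean to obtain a run
length r (um), turn angle theta (rad) and run time dt (min), and (iii)
moves in a straight line by r along a direction tilted by theta from the
previous run (random azimuth, no chirality).  Assigning the triplets
jointly preserves the run-length/run-time correlation that sets each
cell's speed; it is this cell-to-cell heterogeneity that produces
transient super-diffusion in the ensemble.

Event tracks are interpolated onto an even frame grid (3-minute default)
so every trajectory statistic applies to simulated and recorded data
alike.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coarse_grain import ScaledEmpiricals
from .diffusion_stats import LagCurve
from .trajectories import Ensemble, Track

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventTrack:
    """Tumble-event times (min, starting at 0) and positions (um)."""

    times: np.ndarray
    positions: np.ndarray
    means: tuple[float, float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("event times must start at 0 and strictly increase")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: horizon, frame grid, seeding."""

    duration: float
    frame_dt: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.duration > self.frame_dt > 0:
            raise ValueError("need duration > frame_dt > 0")


def sample_run(
    emp: ScaledEmpiricals,
    means: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw one (r, theta, dt) by scaling pooled dimensionless samples.

    One pooled sample per kind is drawn uniformly with replacement and
    multiplied by the walker's own mean.  theta is clipped into [0, pi]
    (clipping is logged; the polar angle cannot exceed pi).
    """
    rbar, tbar, dtbar = means
    if min(rbar, tbar, dtbar) <= 0:
        raise ValueError("mean triplet entries must be positive")
    for name in ("scaled_run_lengths", "scaled_turn_angles", "scaled_run_times"):
        if getattr(emp, name).size == 0:
            raise ValueError(f"empty pooled sample set: {name}")
    r = rbar * float(rng.choice(emp.scaled_run_lengths))
    theta = tbar * float(rng.choice(emp.scaled_turn_angles))
    if theta > np.pi:
        logger.debug("turn angle %.3f rad clipped to pi", theta)
        theta = np.pi
    dt = dtbar * float(rng.choice(emp.scaled_run_times))
    return r, theta, dt


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gram-Schmidt orthonormal pair orthogonal to the unit vector u."""
    seed_axis = np.zeros(3)
    seed_axis[np.argmin(np.abs(u))] = 1.0
    e1 = seed_axis - np.dot(seed_axis, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def step_position(
    x: np.ndarray,
    prev_dir: np.ndarray,
    r: float,
    theta: float,
    phi: float,
) -> np.ndarray:
    """Advance by a run of length r tilted by theta from the previous direction.

    new = x + r cos(theta) prev_dir + r sin(theta)(cos(phi) e1 + sin(phi) e2)
    with (e1, e2) an orthonormal basis of the plane orthogonal to prev_dir.
    The displacement magnitude is exactly r and its angle to prev_dir
    exactly theta, for any azimuth phi.
    """
    prev_dir = np.asarray(prev_dir, dtype=float)
    norm = np.linalg.norm(prev_dir)
    if norm == 0.0:
        raise ValueError("previous direction must be nonzero")
    u = prev_dir / norm
    e1, e2 = _perp_basis(u)
    return (np.asarray(x, dtype=float)
            + r * np.cos(theta) * u
            + r * np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n == 0.0:  # pragma: no cover - measure-zero event
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def simulate_track(
    emp: ScaledEmpiricals,
    means: tuple[float, float, float],
    duration: float,
    rng: np.random.Generator,
) -> EventTrack:
    """Simulate one walker until its cumulative event time reaches duration.

    Starts at the origin with a uniformly random initial direction; each
    run draws a fresh uniform azimuth.  The final event time may overshoot
    the duration (the last run completes).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = [0.0]
    positions = [np.zeros(3)]
    prev_dir = _random_unit_vector(rng)
    t = 0.0
    while t < duration:
        r, theta, dt = sample_run(emp, means, rng)
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        new = step_position(positions[-1], prev_dir, r, theta, phi)
        prev_dir = (new - positions[-1]) / r
        t += dt
        times.append(t)
        positions.append(new)
    return EventTrack(
        times=np.asarray(times),
        positions=np.asarray(positions),
        means=tuple(float(m) for m in means),
    )


def interpolate_uniform(
    event_track: EventTrack,
    frame_dt: float,
    t_max: float | None = None,
    track_id: str = "sim",
) -> Track:
    """Resample an event track onto an even frame grid by linear interpolation.

    Frames are placed at t = 0, frame_dt, 2*frame_dt, ... up to the last
    event time not exceeded (or ``t_max`` if given); within a run the
    walker moves at constant velocity, so linear interpolation is exact.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    t_end = float(event_track.times[-1])
    if t_max is not None:
        t_end = min(t_end, float(t_max))
    n_frames = int(np.floor(t_end / frame_dt + 1e-9)) + 1
    grid = np.arange(n_frames) * frame_dt
    positions = np.column_stack(
        [
            np.interp(grid, event_track.times, event_track.positions[:, c])
            for c in range(3)
        ]
    )
    return Track(track_id=track_id, times=grid, positions=positions)


def simulate_ensemble(
    emp: ScaledEmpiricals,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Simulate one track per empirical mean triplet and frame-interpolate.

    Triplets are assigned jointly (each walker inherits one track's
    complete (rbar, thetabar, dtbar)), preserving the per-cell coupling of
    speed and persistence.  Each track spans exactly
    ``duration/frame_dt + 1`` frames.
    """
    if emp.mean_triplets.shape[0] == 0:
        raise ValueError("no mean triplets to simulate from")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tracks = []
    for i, means in enumerate(emp.mean_triplets):
        event = simulate_track(emp, tuple(means), config.duration, rng)
        tracks.append(
            interpolate_uniform(
                event, config.frame_dt, t_max=config.duration,
                track_id=f"sim-{i:03d}",
            )
        )
    return Ensemble(tracks=tuple(tracks), nominal_dt=config.frame_dt)


def estimate_crossover(
    curve: LagCurve,
    window: int = 5,
    tol: float = 0.1,
) -> float | None:
    """Estimate the lag at which a TAMSD curve becomes Fickian (slope 1).

    The local log-log slope is fitted by OLS in a sliding window of
    ``window`` lag points; the crossover is the smallest window-start lag
    from which the slope enters and remains within ``tol`` of 1.  Returns
    None when the slope never settles.
    """
    if window < 2:
        raise ValueError("window must span at least 2 lag points")
    if np.any(curve.values <= 0):
        raise ValueError("curve values must be positive")
    n = curve.lags.size
    if n < window:
        return None
    log_l = np.log(curve.lags)
    log_v = np.log(curve.values)
    slopes = np.array(
        [
            np.polyfit(log_l[j : j + window], log_v[j : j + window], 1)[0]
            for j in range(n - window + 1)
        ]
    )
    ok = np.abs(slopes - 1.0) <= tol
    # smallest start index from which every later window is Fickian
    for j in range(ok.size):
        if ok[j:].all():
            return float(curve.lags[j])
    return None
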