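"""Trajectory coarse-graining and run/turn decomposition.

Cell-centroid tracks contain short-range jitter unrelated to whole-cell
translocation.  Coarse-graining retains an ordered subset of frames such
that consecutive retained positions are separated by more than a threshold
``R_thresh`` (default 7.2 um, about one cell diameter).  Between consecutive
retained points a *run* is defined (length r in um, time dt in minutes), and
between consecutive runs a *turn angle* theta in [0, pi].

Per-track means (rbar, thetabar, dtbar) capture the cell-to-cell
heterogeneity; dividing each track's samples by its own means and pooling
across tracks yields the dimensionless *scaled empirical distributions* that
drive the run-and-tumble simulator.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .trajectories import Ensemble, Track

logger = logging.getLogger(__name__)

#: Default retention threshold, microns (about one cell diameter).
DEFAULT_R_THRESH = 7.2


@dataclass(frozen=True)
class CoarseTrack:
    """Ordered subset of a track's frames with consecutive spacing > R."""

    source_id: str
    indices: np.ndarray
    times: np.ndarray
    positions: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.indices.shape[0])


@dataclass(frozen=True)
class RunDecomposition:
    """Runs, turn angles and their per-track means for one coarse track.

    ``run_lengths`` (um) and ``run_times`` (min) have one entry per
    consecutive retained pair; ``turn_angles`` (rad, in [0, pi]) one entry
    per consecutive run pair.  A coarse track with fewer than two retained
    points yields an empty decomposition (``n_runs == 0``).
    """

    source_id: str
    run_lengths: np.ndarray
    run_times: np.ndarray
    turn_angles: np.ndarray

    def __post_init__(self) -> None:
        rl = np.asarray(self.run_lengths, dtype=float)
        rt = np.asarray(self.run_times, dtype=float)
        ta = np.asarray(self.turn_angles, dtype=float)
        if rl.shape != rt.shape:
            raise ValueError("run_lengths and run_times length mismatch")
        if rl.size and (np.any(rl <= 0) or np.any(rt <= 0)):
            raise ValueError("run lengths and times must be positive")
        if ta.size and (np.any(ta < 0) or np.any(ta > np.pi)):
            raise ValueError("turn angles must lie in [0, pi]")
        if rl.size >= 1 and ta.size != max(rl.size - 1, 0):
            raise ValueError("need exactly n_runs - 1 turn angles")
        object.__setattr__(self, "run_lengths", rl)
        object.__setattr__(self, "run_times", rt)
        object.__setattr__(self, "turn_angles", ta)

    @property
    def n_runs(self) -> int:
        return int(self.run_lengths.size)

    @property
    def mean_run_length(self) -> float:
        return float(np.mean(self.run_lengths))

    @property
    def mean_run_time(self) -> float:
        return float(np.mean(self.run_times))

    @property
    def mean_turn_angle(self) -> float:
        if self.turn_angles.size == 0:
            raise ValueError(
                f"track {self.source_id!r} has no turn angles; mean undefined"
            )
        return float(np.mean(self.turn_angles))


@dataclass(frozen=True)
class ScaledEmpiricals:
    """Pooled dimensionless samples plus the per-track mean triplets.

    ``mean_triplets`` is an ``(n_tracks, 3)`` array of (rbar um, thetabar
    rad, dtbar min), one complete triplet per contributing track, in input
    order.  The pooled samples are each track's runs/angles/times divided by
    that track's own mean, so within a contributing track every scaled kind
    averages exactly 1.
    """

    scaled_run_lengths: np.ndarray
    scaled_turn_angles: np.ndarray
    scaled_run_times: np.ndarray
    mean_triplets: np.ndarray
    track_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("scaled_run_lengths", "scaled_turn_angles", "scaled_run_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size and np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        triplets = np.asarray(self.mean_triplets, dtype=float)
        if triplets.size == 0 or triplets.ndim != 2 or triplets.shape[1] != 3:
            raise ValueError("mean_triplets must be a nonempty (n, 3) array")
        object.__setattr__(self, "mean_triplets", triplets)

    @property
    def n_tracks(self) -> int:
        return int(self.mean_triplets.shape[0])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "scaled_run_lengths": self.scaled_run_lengths.tolist(),
            "scaled_turn_angles": self.scaled_turn_angles.tolist(),
            "scaled_run_times": self.scaled_run_times.tolist(),
            "mean_triplets": self.mean_triplets.tolist(),
            "track_ids": list(self.track_ids),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaledEmpiricals":
        payload = json.loads(Path(path).read_text())
        return cls(
            scaled_run_lengths=np.asarray(payload["scaled_run_lengths"]),
            scaled_turn_angles=np.asarray(payload["scaled_turn_angles"]),
            scaled_run_times=np.asarray(payload["scaled_run_times"]),
            mean_triplets=np.asarray(payload["mean_triplets"]),
            track_ids=tuple(payload.get("track_ids", ())),
        )


def coarse_grain(track: Track, r_thresh: float = DEFAULT_R_THRESH) -> CoarseTrack:
    """Greedy threshold coarse-graining of one track.

    Frame 0 is always retained; thereafter each retained frame is the
    earliest frame whose Euclidean distance from the previously retained
    position strictly exceeds ``r_thresh``.  Trailing frames that never
    exceed the threshold are dropped.  A single-point result is legal.
    """
    if r_thresh < 0:
        raise ValueError("r_thresh must be >= 0")
    pos = track.positions
    keep = [0]
    last = pos[0]
    for i in range(1, pos.shape[0]):
        if math.dist(pos[i], last) > r_thresh:
            keep.append(i)
            last = pos[i]
    idx = np.asarray(keep, dtype=int)
    return CoarseTrack(
        source_id=track.track_id,
        indices=idx,
        times=track.times[idx],
        positions=pos[idx],
    )


def turn_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Polar angle in [0, pi] between two run vectors.

    Computed as arccos of the clamped normalized dot product
    cos(theta) = u.v / (|u||v|).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("turn_angle undefined for zero-length run vector")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def decompose_runs(coarse: CoarseTrack) -> RunDecomposition:
    """Decompose a coarse track into runs and turn angles.

    One run per consecutive retained pair; one angle per consecutive run
    pair.  A coarse track with fewer than two points yields an empty
    decomposition (excluded from pooling downstream).
    """
    if coarse.n_points < 2:
        logger.debug("track %s: single-point coarse track, empty decomposition",
                     coarse.source_id)
        return RunDecomposition(
            source_id=coarse.source_id,
            run_lengths=np.empty(0),
            run_times=np.empty(0),
            turn_angles=np.empty(0),
        )
    steps = np.diff(coarse.positions, axis=0)
    run_lengths = np.linalg.norm(steps, axis=1)
    run_times = np.diff(coarse.times)
    angles = np.array(
        [turn_angle(steps[i], steps[i + 1]) for i in range(steps.shape[0] - 1)]
    )
    return RunDecomposition(
        source_id=coarse.source_id,
        run_lengths=run_lengths,
        run_times=run_times,
        turn_angles=angles,
    )


def build_scaled_empiricals(
    decomps: Iterable[RunDecomposition],
) -> ScaledEmpiricals:
    """Pool per-track scaled samples into dimensionless empirical distributions.

    Each track's run lengths, turn angles and run times are divided by that
    track's own mean before pooling, which removes the cell-to-cell scale
    and leaves the common shape of the distributions.  Only tracks with at
    least one turn angle contribute a complete (rbar, thetabar, dtbar) mean
    triplet; tracks with runs but no angles contribute their run samples but
    are excluded from ``mean_triplets`` (logged), because the simulator
    needs complete triplets.
    """
    decomps = list(decomps)
    usable = [d for d in decomps if d.n_runs >= 1]
    if not usable:
        raise ValueError("no decomposition with at least one run")
    scaled_r: list[np.ndarray] = []
    scaled_t: list[np.ndarray] = []
    scaled_a: list[np.ndarray] = []
    triplets: list[tuple[float, float, float]] = []
    ids: list[str] = []
    for d in usable:
        scaled_r.append(d.run_lengths / d.mean_run_length)
        scaled_t.append(d.run_times / d.mean_run_time)
        if d.turn_angles.size >= 1:
            tbar = d.mean_turn_angle
            if tbar > 0:
                scaled_a.append(d.turn_angles / tbar)
            else:  # all-zero angles: scaled shape undefined, treat as ones
                scaled_a.append(np.ones_like(d.turn_angles))
            triplets.append((d.mean_run_length, tbar, d.mean_run_time))
            ids.append(d.source_id)
        else:
            logger.info(
                "track %s: no turn angles; excluded from mean_triplets",
                d.source_id,
            )
    if not triplets:
        raise ValueError("no track contributed a complete mean triplet")
    return ScaledEmpiricals(
        scaled_run_lengths=np.concatenate(scaled_r),
        scaled_turn_angles=(
            np.concatenate(scaled_a) if scaled_a else np.empty(0)
        ),
        scaled_run_times=np.concatenate(scaled_t),
        mean_triplets=np.asarray(triplets),
        track_ids=tuple(ids),
    )


def decompose_ensemble(
    ensemble: Ensemble, r_thresh: float = DEFAULT_R_THRESH
) -> list[RunDecomposition]:
    """Coarse-grain and decompose every track of an ensemble."""
    return [decompose_runs(coarse_grain(t, r_thresh)) for t in ensemble]


def calibrate_threshold(
    ensemble: Ensemble,
    candidates: Sequence[float],
    sim_duration: float | None = None,
    lag_range: tuple[float, float] = (3.0, 150.0),
    seed: int | None = None,
) -> tuple[float, dict[float, float]]:
    """Select the coarse-graining threshold by TAMSD matching.

    For each candidate R the ensemble is coarse-grained, scaled empiricals
    are rebuilt, a run-and-tumble ensemble is simulated from them, and the
    objective is the root sum of squared differences between the simulated
    and input ensemble TAMSD curves on a common lag grid (linear space,
    default lags 3-150 min).  Returns the argmin candidate and the full
    objective table; candidates yielding no usable runs score infinity.
    """
    from . import diffusion_stats as ds
    from . import rtb_sim

    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    dt = ensemble.nominal_dt
    max_lag = min(lag_range[1], min(t.duration for t in ensemble))
    lags = np.arange(dt, max_lag + 1e-9, dt)
    lags = lags[lags >= lag_range[0]]
    exp_curve = ds.ensemble_average(
        [ds.tamsd_curve(t, lags) for t in ensemble]
    )
    duration = sim_duration if sim_duration is not None else max(
        t.duration for t in ensemble
    )
    objectives: dict[float, float] = {}
    for r in candidates:
        try:
            emp = build_scaled_empiricals(decompose_ensemble(ensemble, r))
        except ValueError:
            logger.warning("threshold %g um: no usable runs, skipped", r)
            objectives[float(r)] = float("inf")
            continue
        config = rtb_sim.SimConfig(duration=duration, frame_dt=dt, seed=seed)
        sim = rtb_sim.simulate_ensemble(emp, config)
        sim_curve = ds.ensemble_average(
            [ds.tamsd_curve(t, exp_curve.lags) for t in sim]
        )
        objectives[float(r)] = float(
            np.sqrt(np.sum((sim_curve.values - exp_curve.values) ** 2))
        )
    finite = {r: o for r, o in objectives.items() if np.isfinite(o)}
    if not finite:
        raise ValueError("every candidate threshold yielded zero usable runs")
    best = min(finite, key=finite.get)
    return best, objectives
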