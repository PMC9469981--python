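"""Grid-based superstatistical Bayesian inference of motility parameters.

Cell velocities (per-frame displacements, um/frame) are modeled as an AR-1
persistent random walk,

    v_t = q_t v_{t-1} + a_t n_t ,

with time-varying persistence q_t in (-1, 1), activity a_t in (0, a_max],
and unit-variance Gaussian noise n_t applied per component with shared
scalar parameters.  The pair (a_t, q_t) is treated as the hidden state of a
hidden Markov model over a discretized 200 x 200 parameter grid and
inferred with scaled forward-backward recursions.  Instead of a parametric
transition law, the prior is propagated by a deliberately generic two-step
K transform: a probability floor p_min (absorbs abrupt regime changes)
followed by a uniform box convolution of radius R_box grid cells (absorbs
gradual drift).  The hyperparameters (p_min, R_box) are chosen by
maximizing the model evidence (empirical Bayes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectories import Track

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParameterGrid:
    """Cell centers of the discretized (a, q) parameter space.

    Activity cells tile (0, a_max]; persistence cells tile (-1, 1).  Grids
    are stored as (n_a, n_q) arrays: rows index activity, columns
    persistence.
    """

    a_centers: np.ndarray
    q_centers: np.ndarray
    a_max: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a_centers, dtype=float)
        q = np.asarray(self.q_centers, dtype=float)
        if np.any(np.diff(a) <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if a[0] <= 0 or not self.a_max > 0:
            raise ValueError("activity axis must be positive")
        if q[0] <= -1 or q[-1] >= 1:
            raise ValueError("persistence axis must lie inside (-1, 1)")
        object.__setattr__(self, "a_centers", a)
        object.__setattr__(self, "q_centers", q)

    @classmethod
    def regular(
        cls, a_max: float, n_a: int = 200, n_q: int = 200
    ) -> "ParameterGrid":
        """Cell centers of a regular n_a x n_q tiling of (0, a_max] x (-1, 1)."""
        a_edges = np.linspace(0.0, a_max, n_a + 1)
        q_edges = np.linspace(-1.0, 1.0, n_q + 1)
        return cls(
            a_centers=0.5 * (a_edges[:-1] + a_edges[1:]),
            q_centers=0.5 * (q_edges[:-1] + q_edges[1:]),
            a_max=float(a_max),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.a_centers.size, self.q_centers.size)

    @property
    def n_cells(self) -> int:
        return self.a_centers.size * self.q_centers.size

    @property
    def voxel(self) -> float:
        """Cell area da * dq (the measure entering the evidence sum)."""
        da = self.a_centers[1] - self.a_centers[0]
        dq = self.q_centers[1] - self.q_centers[0]
        return float(da * dq)


@dataclass(frozen=True)
class SuperstatResult:
    """Per-time posterior summaries plus the time-averaged posterior grid."""

    a_mean: np.ndarray
    a_lo: np.ndarray
    a_hi: np.ndarray
    q_mean: np.ndarray
    q_lo: np.ndarray
    q_hi: np.ndarray
    time_avg_posterior: np.ndarray
    log_evidence: float | None = None
    hyperparameters: tuple[float, int] | None = None


def a_max_from_velocities(velocities: np.ndarray, margin: float = 1.05) -> float:
    """Data-driven activity bound: margin times the largest per-frame speed."""
    speeds = np.linalg.norm(np.asarray(velocities, dtype=float), axis=1)
    top = float(speeds.max())
    if top <= 0:
        raise ValueError("all velocities are zero; a_max undefined")
    return margin * top


def velocities_from_track(track: Track) -> np.ndarray:
    """Per-frame displacement vectors v_t = r_t - r_{t-1} (um/frame)."""
    if track.n_frames < 3:
        raise ValueError("need at least 3 frames for velocity inference")
    track.frame_dt()  # raises on non-uniform sampling
    return np.diff(track.positions, axis=0)


def _log_likelihood_grid(
    v: np.ndarray, v_prev: np.ndarray, grid: ParameterGrid
) -> np.ndarray:
    """Log of the AR-1 one-step likelihood on the (a, q) grid.

    At each cell the three velocity components are independent normals with
    mean q * v_prev and standard deviation a.
    """
    q = grid.q_centers
    res2 = (
        float(np.dot(v, v))
        - 2.0 * q * float(np.dot(v, v_prev))
        + q**2 * float(np.dot(v_prev, v_prev))
    )
    a = grid.a_centers[:, None]
    return -1.5 * _LOG2PI - 3.0 * np.log(a) - res2[None, :] / (2.0 * a**2)


def step_likelihood(
    v: np.ndarray, v_prev: np.ndarray, grid: ParameterGrid
) -> np.ndarray:
    """Unnormalized one-step likelihood grid (max-scaled to avoid underflow)."""
    log_l = _log_likelihood_grid(
        np.asarray(v, dtype=float), np.asarray(v_prev, dtype=float), grid
    )
    return np.exp(log_l - log_l.max())


def _box_mean_1d(p: np.ndarray, r: int, axis: int) -> np.ndarray:
    """Truncated uniform box mean of radius r along one axis.

    out[j] is the mean of p over the in-bounds window [j - r, j + r]; the
    kernel is truncated at the grid edges (off-grid mass is redistributed by
    the global renormalization that follows in :func:`k_transform`).  A
    uniform grid is an exact fixed point.
    """
    n = p.shape[axis]
    idx = np.arange(n)
    hi = np.minimum(idx + r, n - 1)
    lo = idx - r
    counts = hi - np.maximum(lo, 0) + 1
    shape = [1, 1]
    shape[axis] = n
    c = np.cumsum(p, axis=axis)
    out = np.take(c, hi, axis=axis)
    mask = (lo >= 1).astype(float)
    out = out - np.take(c, np.maximum(lo - 1, 0), axis=axis) * mask.reshape(shape)
    return out / counts.reshape(shape)


def k_transform(p: np.ndarray, p_min: float, r_box: int) -> np.ndarray:
    """Two-step generic prior transform on a normalized probability grid.

    First a probability floor p_min is applied cellwise and the grid
    renormalized (permitting abrupt parameter jumps); then the grid is
    convolved with a uniform (2 R_box + 1)^2 box, spreading each cell's
    mass over its in-bounds neighborhood (gradual drift).  Output is
    normalized.
    """
    p = np.asarray(p, dtype=float)
    if p_min < 0:
        raise ValueError("p_min must be nonnegative")
    if p_min >= 1.0 / p.size:
        raise ValueError(
            "p_min at or above the uniform weight would erase all structure"
        )
    if r_box < 0:
        raise ValueError("r_box must be nonnegative")
    out = np.maximum(p, p_min)
    out = out / out.sum()
    if r_box > 0:
        out = _box_mean_1d(out, r_box, axis=0)
        out = _box_mean_1d(out, r_box, axis=1)
        out = out / out.sum()
    return out


def forward_backward(
    velocities: np.ndarray,
    grid: ParameterGrid | None = None,
    p_min: float = 1e-6,
    r_box: int = 2,
    return_posteriors: bool = True,
) -> tuple[np.ndarray | None, float]:
    """Scaled forward-backward inference of (a_t, q_t) on the grid.

    The forward recursion starts from a uniform prior and alternates
    likelihood multiplication with the K transform; the backward recursion
    runs independently from the end.  The per-time posterior is
    proportional to L_t * K[alpha_{t-1}] * K[L_{t+1} beta_{t+1}],
    normalized on the grid.  The log evidence is accumulated from the
    forward normalization constants together with the voxel measure
    (equivalent to summing the unnormalized posterior density over the
    grid).

    Returns ``(posteriors, log_evidence)`` where posteriors has shape
    ``(T - 1, n_a, n_q)`` (one grid per velocity transition), or ``None``
    when ``return_posteriors`` is False (evidence-only pass, cheaper).
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("velocities must be an (T >= 2, 3) array")
    if grid is None:
        grid = ParameterGrid.regular(a_max_from_velocities(v))
    n_steps = v.shape[0] - 1
    n_cells = grid.n_cells
    uniform = np.full(grid.shape, 1.0 / n_cells)

    def log_l(t: int) -> np.ndarray:
        return _log_likelihood_grid(v[t + 1], v[t], grid)

    # Forward pass: alpha_t and the predicted priors K[alpha_{t-1}].
    # Priors are stored as cell masses (density times voxel), so the
    # accumulated normalizers equal the evidence sum over the grid with the
    # voxel measure already included.
    prior = uniform
    priors_f = (
        np.empty((n_steps, *grid.shape), dtype=np.float32)
        if return_posteriors
        else None
    )
    log_z = 0.0
    for t in range(n_steps):
        ll = log_l(t)
        shift = ll.max()
        m = np.exp(ll - shift) * prior
        c = m.sum()
        if c <= 0.0 or not np.isfinite(c):
            raise ValueError(f"degenerate likelihood at time index {t}")
        log_z += float(np.log(c) + shift)
        alpha = m / c
        if priors_f is not None:
            priors_f[t] = prior
        prior = k_transform(alpha, p_min, r_box)
    if not return_posteriors:
        return None, log_z

    # Backward pass: beta_t = K[L_{t+1} beta_{t+1}], uniform at the end.
    betas = np.empty((n_steps, *grid.shape), dtype=np.float32)
    beta = uniform
    betas[n_steps - 1] = beta
    for t in range(n_steps - 2, -1, -1):
        ll = log_l(t + 1)
        m = np.exp(ll - ll.max()) * betas[t + 1]
        s = m.sum()
        if s <= 0.0 or not np.isfinite(s):
            raise ValueError(f"degenerate likelihood at time index {t + 1}")
        betas[t] = k_transform(m / s, p_min, r_box)

    posteriors = np.empty((n_steps, *grid.shape), dtype=np.float32)
    for t in range(n_steps):
        ll = log_l(t)
        post = np.exp(ll - ll.max()) * priors_f[t] * betas[t]
        s = post.sum()
        if s <= 0.0 or not np.isfinite(s):
            raise ValueError(f"degenerate posterior at time index {t}")
        posteriors[t] = post / s
    return posteriors, log_z


def _marginal_summary(
    mass: np.ndarray, centers: np.ndarray
) -> tuple[float, float, float]:
    """Mean and central 50% interval of a discrete marginal.

    The interval bounds are the 25th/75th percentiles of the piecewise-
    linear CDF built on the cell edges (mass uniform within a cell), so a
    uniform marginal on (-1, 1) yields exactly (-0.5, 0.5).
    """
    mass = np.asarray(mass, dtype=float)
    mass = mass / mass.sum()
    mean = float(np.dot(centers, mass))
    half = 0.5 * (centers[1] - centers[0])
    edges = np.concatenate([[centers[0] - half], centers + half])
    cdf = np.concatenate([[0.0], np.cumsum(mass)])
    lo = float(np.interp(0.25, cdf, edges))
    hi = float(np.interp(0.75, cdf, edges))
    return mean, lo, hi


def posterior_summaries(
    posteriors: np.ndarray,
    grid: ParameterGrid,
    log_evidence: float | None = None,
    hyperparameters: tuple[float, int] | None = None,
) -> SuperstatResult:
    """Marginal means and 50% credible intervals per time, plus the grid mean.

    Activity marginalizes over persistence and vice versa; intervals are
    central (25th-75th percentile), so they always contain the marginal
    median.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.ndim != 3 or posteriors.shape[0] == 0:
        raise ValueError("posteriors must be a nonempty (T, n_a, n_q) array")
    n = posteriors.shape[0]
    a_mean = np.empty(n)
    a_lo = np.empty(n)
    a_hi = np.empty(n)
    q_mean = np.empty(n)
    q_lo = np.empty(n)
    q_hi = np.empty(n)
    for t in range(n):
        a_mean[t], a_lo[t], a_hi[t] = _marginal_summary(
            posteriors[t].sum(axis=1), grid.a_centers
        )
        q_mean[t], q_lo[t], q_hi[t] = _marginal_summary(
            posteriors[t].sum(axis=0), grid.q_centers
        )
    return SuperstatResult(
        a_mean=a_mean, a_lo=a_lo, a_hi=a_hi,
        q_mean=q_mean, q_lo=q_lo, q_hi=q_hi,
        time_avg_posterior=posteriors.mean(axis=0),
        log_evidence=log_evidence,
        hyperparameters=hyperparameters,
    )


def select_hyperparameters(
    velocities: np.ndarray,
    grid: ParameterGrid | None = None,
    candidates: Sequence[tuple[float, int]] = ((1e-6, 1), (1e-6, 2), (1e-5, 2)),
) -> tuple[tuple[float, int], list[tuple[float, int, float]]]:
    """Empirical-Bayes choice of (p_min, R_box) by maximum model evidence.

    Runs an evidence-only forward pass per candidate and returns the argmax
    pair along with the full (p_min, r_box, log_evidence) table.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    v = np.asarray(velocities, dtype=float)
    if grid is None:
        grid = ParameterGrid.regular(a_max_from_velocities(v))
    table: list[tuple[float, int, float]] = []
    for p_min, r_box in candidates:
        _, log_ev = forward_backward(
            v, grid, p_min=p_min, r_box=r_box, return_posteriors=False
        )
        table.append((float(p_min), int(r_box), log_ev))
    best = max(table, key=lambda row: row[2])
    return (best[0], best[1]), table


def infer_track(
    track: Track,
    grid: ParameterGrid | None = None,
    p_min: float = 1e-6,
    r_box: int = 2,
) -> SuperstatResult:
    """Convenience wrapper: velocities, forward-backward and summaries."""
    v = velocities_from_track(track)
    if grid is None:
        grid = ParameterGrid.regular(a_max_from_velocities(v))
    posteriors, log_ev = forward_backward(v, grid, p_min=p_min, r_box=r_box)
    return posterior_summaries(
        posteriors, grid, log_evidence=log_ev,
        hyperparameters=(float(p_min), int(r_box)),
    )
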