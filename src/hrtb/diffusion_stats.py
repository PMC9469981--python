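"""Anomalous-diffusion statistics for trajectory ensembles.

The central estimator is the time-averaged mean squared displacement
(TAMSD) of a single track,

    tamsd_i(lag) = mean over t of |r(t + lag) - r(t)|^2 ,

averaged over all overlapping frame pairs separated by the lag, and its
ensemble average over tracks.  A power-law fit tamsd ~ lag^alpha classifies
the motion (alpha = 1 Fickian, alpha > 1 super-diffusive).  Complementary
statistics characterize the displacement distributions: a scaling-collapse
exponent beta chosen by minimizing the maximum pairwise Wasserstein
distance among rescaled distributions eta = dx / lag^beta; a generalized
Gaussian maximum-likelihood fit whose shape parameter gamma measures
tailedness (gamma = 2 Gaussian, gamma = 1 Laplace); and the
non-Gaussianity parameter

    G(lag) = d/(d+2) * <tamsd4> / <tamsd2>^2 - 1 ,

zero for Gaussian displacements and positive for fat tails.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .coarse_grain import RunDecomposition
from .trajectories import Ensemble, Track

logger = logging.getLogger(__name__)

#: Lag times (minutes) used for displacement-distribution analyses.
DEFAULT_LAGS = (3.0, 6.0, 15.0, 30.0, 60.0, 120.0)

#: Default search grid for the collapse exponent beta.
DEFAULT_BETA_GRID = np.round(np.arange(0.30, 1.20 + 1e-9, 0.005), 3)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class LagCurve:
    """Values of a lag-dependent statistic on a strictly increasing lag grid."""

    lags: np.ndarray
    values: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        n = np.asarray(self.n_contributing, dtype=int)
        if not (lags.shape == values.shape == n.shape):
            raise ValueError("lags, values, n_contributing must share a shape")
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_contributing", n)


@dataclass(frozen=True)
class ScalingFit:
    """Power-law exponent fitted by OLS in log-log space."""

    alpha: float
    log_intercept: float
    lag_range: tuple[float, float]
    fit_stderr: float


@dataclass(frozen=True)
class CollapseResult:
    """Collapse exponent beta and the criterion curve over the search grid."""

    beta: float
    beta_grid: np.ndarray
    criterion: np.ndarray


@dataclass(frozen=True)
class GenGaussParams:
    """Generalized Gaussian MLE: shape gamma, scale sigma (um), log-likelihood."""

    gamma: float
    sigma: float
    loglik: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be finite and positive")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and positive")


def _lag_to_frames(track: Track, lag: float) -> int:
    dt = track.frame_dt()
    k = lag / dt
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-6 * max(1.0, k):
        raise ValueError(
            f"lag {lag} min is not a positive multiple of the frame interval "
            f"{dt} min"
        )
    return k_int


def tamsd_moment(track: Track, lag: float, p: int = 2) -> float:
    """Time-averaged p-th moment of the displacement magnitude at one lag.

    Discrete estimator: the mean of |r(t + lag) - r(t)|^p over all
    overlapping frame pairs separated by the lag.  p must be 2 (TAMSD) or 4
    (the fourth-moment analogue used by the non-Gaussianity parameter).
    """
    if p not in (2, 4):
        raise ValueError("moment order p must be 2 or 4")
    k = _lag_to_frames(track, lag)
    if k >= track.n_frames - 1:
        raise ValueError(
            f"lag {lag} min is not shorter than track duration "
            f"{track.duration} min"
        )
    disp = track.positions[k:] - track.positions[:-k]
    return float(np.mean(np.linalg.norm(disp, axis=1) ** p))


def tamsd_curve(track: Track, lags: Sequence[float], p: int = 2) -> LagCurve:
    """TAMSD-type moments of one track over a lag grid."""
    lags = np.asarray(sorted(lags), dtype=float)
    values = np.array([tamsd_moment(track, lag, p) for lag in lags])
    return LagCurve(lags=lags, values=values,
                    n_contributing=np.ones_like(lags, dtype=int))


def ensemble_average(curves: Iterable[LagCurve]) -> LagCurve:
    """Unweighted per-lag mean over curves, on the intersection of lag grids."""
    curves = list(curves)
    if not curves:
        raise ValueError("empty curve collection")
    common = set(np.round(curves[0].lags, 9).tolist())
    for c in curves[1:]:
        common &= set(np.round(c.lags, 9).tolist())
    if not common:
        raise ValueError("lag grids have empty intersection")
    lags = np.array(sorted(common))
    stacked = np.empty((len(curves), lags.size))
    for i, c in enumerate(curves):
        idx = {round(l, 9): j for j, l in enumerate(c.lags)}
        stacked[i] = [c.values[idx[round(l, 9)]] for l in lags]
    return LagCurve(
        lags=lags,
        values=stacked.mean(axis=0),
        n_contributing=np.full(lags.size, len(curves), dtype=int),
    )


def fit_power_law(
    curve: LagCurve, lag_range: tuple[float, float] = (3.0, 150.0)
) -> ScalingFit:
    """OLS fit of log(value) on log(lag); the slope is the exponent alpha."""
    lo, hi = lag_range
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 lag points inside the fit range")
    vals = curve.values[mask]
    if np.any(vals <= 0):
        raise ValueError("nonpositive curve values inside the fit range")
    res = stats.linregress(np.log(curve.lags[mask]), np.log(vals))
    return ScalingFit(
        alpha=float(res.slope),
        log_intercept=float(res.intercept),
        lag_range=(float(lo), float(hi)),
        fit_stderr=float(res.stderr),
    )


def lagged_displacements(
    ensemble: Ensemble,
    axis: str,
    lag: float,
    min_duration: float | None = None,
) -> np.ndarray:
    """Pool single-axis displacements dx = x(t + lag) - x(t) over tracks.

    Tracks shorter than the lag contribute nothing.  Passing
    ``min_duration`` (typically the largest analysis lag) restricts pooling
    to tracks of at least that duration, so every lag of a multi-lag
    analysis draws from the same track set.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    col = _AXES[axis]
    samples = []
    for t in ensemble:
        if min_duration is not None and t.duration < min_duration:
            continue
        if t.duration < lag:
            continue
        k = _lag_to_frames(t, lag)
        if k >= t.n_frames:
            continue
        x = t.positions[:, col]
        samples.append(x[k:] - x[:-k])
    if not samples:
        raise ValueError(f"no track long enough for lag {lag} min")
    return np.concatenate(samples)


def wasserstein_1d(u: np.ndarray, v: np.ndarray) -> float:
    """First-order Wasserstein distance between two empirical distributions.

    Equals the integral of |U(x) - V(x)| over the real line, with U, V the
    empirical CDFs; symmetric, nonnegative, zero iff the empirical
    distributions coincide.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise ValueError("empty sample set")
    return float(stats.wasserstein_distance(u, v))


def optimize_collapse(
    ensemble: Ensemble,
    axis: str = "x",
    lags: Sequence[float] = DEFAULT_LAGS,
    beta_grid: Sequence[float] | None = None,
) -> CollapseResult:
    """Select the collapse exponent beta of the rescaled displacements.

    For each candidate beta, every lag's displacement samples are rescaled
    to eta = dx / lag^beta and the Wasserstein distance is computed for
    every unordered pair of lags; the criterion is the maximum over pairs.
    The returned beta minimizes that criterion (the distributions at all
    lags fall onto one master curve).  Pooling is restricted to tracks at
    least as long as the largest lag.
    """
    lags = sorted(float(l) for l in lags)
    if len(lags) < 2:
        raise ValueError("need at least 2 lags for a collapse")
    grid = (np.asarray(beta_grid, dtype=float) if beta_grid is not None
            else DEFAULT_BETA_GRID.copy())
    if grid.size == 0:
        raise ValueError("beta grid is empty")
    max_lag = max(lags)
    samples = {
        lag: lagged_displacements(ensemble, axis, lag, min_duration=max_lag)
        for lag in lags
    }
    criterion = np.empty(grid.size)
    for i, beta in enumerate(grid):
        rescaled = [samples[lag] / lag**beta for lag in lags]
        worst = 0.0
        for a in range(len(lags)):
            for b in range(a + 1, len(lags)):
                worst = max(worst, wasserstein_1d(rescaled[a], rescaled[b]))
        criterion[i] = worst
    best = int(np.argmin(criterion))
    return CollapseResult(beta=float(grid[best]), beta_grid=grid,
                          criterion=criterion)


def fit_generalized_gaussian(
    samples: np.ndarray, gamma_bounds: tuple[float, float] = (0.2, 5.0)
) -> GenGaussParams:
    """Profile MLE of the generalized Gaussian with location fixed at 0.

    Density: gamma / (2 sigma Gamma(1/gamma)) * exp(-|x / sigma|^gamma).
    For fixed gamma the scale MLE has the closed form
    sigma_hat = (gamma/n * sum |x|^gamma)^(1/gamma); the profile
    log-likelihood is then maximized over gamma by bounded 1-D search.
    Displacement distributions are mean-zero by symmetry, hence the fixed
    location.
    """
    x = np.abs(np.asarray(samples, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(samples) == 0:
        raise ValueError("degenerate samples (all identical)")

    def profile_negloglik(gamma: float) -> float:
        s = np.sum(x**gamma)
        sigma = (gamma * s / n) ** (1.0 / gamma)
        # at sigma_hat, sum |x/sigma|^gamma = n / gamma
        ll = (n * np.log(gamma) - n * np.log(2.0) - n * np.log(sigma)
              - n * gammaln(1.0 / gamma) - n / gamma)
        return -ll

    res = optimize.minimize_scalar(
        profile_negloglik, bounds=gamma_bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"generalized Gaussian MLE failed: {res.message}")
    gamma = float(res.x)
    sigma = float((gamma * np.sum(x**gamma) / n) ** (1.0 / gamma))
    return GenGaussParams(gamma=gamma, sigma=sigma, loglik=float(-res.fun))


def non_gaussianity(
    ensemble: Ensemble, lags: Sequence[float], d: int = 3
) -> LagCurve:
    """Non-Gaussianity parameter G(lag) from time-averaged moments.

    G = d/(d+2) * <tamsd4> / <tamsd2>^2 - 1, where the angle brackets are
    ensemble means of the per-track time-averaged fourth and second moments
    of the d-dimensional displacement magnitude (the first d coordinates).
    G = 0 for Gaussian displacements, G > 0 for fat tails.  Tracks shorter
    than the largest lag are excluded so all lags use the same track set.
    """
    if d not in (1, 2, 3):
        raise ValueError("embedding dimension d must be 1, 2 or 3")
    lags = np.asarray(sorted(float(l) for l in lags))
    max_lag = float(lags[-1])
    tracks = [t for t in ensemble if t.duration >= max_lag]
    if not tracks:
        raise ValueError("no track long enough for the largest lag")
    values = np.empty(lags.size)
    for i, lag in enumerate(lags):
        m2, m4 = [], []
        for t in tracks:
            k = _lag_to_frames(t, lag)
            disp = t.positions[k:, :d] - t.positions[:-k, :d]
            mag2 = np.sum(disp**2, axis=1)
            m2.append(np.mean(mag2))
            m4.append(np.mean(mag2**2))
        mean2 = float(np.mean(m2))
        if mean2 == 0.0:
            raise ValueError(f"zero second moment at lag {lag} min")
        values[i] = d / (d + 2) * float(np.mean(m4)) / mean2**2 - 1.0
    return LagCurve(lags=lags, values=values,
                    n_contributing=np.full(lags.size, len(tracks), dtype=int))


def split_by_persistence(
    decomps: Iterable[RunDecomposition], threshold: float = 1.5
) -> tuple[list[str], list[str]]:
    """Split track ids into persistent / less-persistent groups.

    A track is persistent when its mean turn angle thetabar is strictly
    below the threshold (radians); thetabar >= threshold, including
    exactly at the boundary, goes to the less-persistent group.  Tracks
    without turn angles are skipped.
    """
    if not (0.0 < threshold < np.pi):
        raise ValueError("threshold must lie in (0, pi)")
    persistent: list[str] = []
    diffusive: list[str] = []
    for d in decomps:
        if d.turn_angles.size == 0:
            logger.info("track %s: no turn angles, skipped in split", d.source_id)
            continue
        (persistent if d.mean_turn_angle < threshold else diffusive).append(
            d.source_id
        )
    return persistent, diffusive
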