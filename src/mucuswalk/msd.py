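"""Ensemble mean-squared-displacement estimation and log–log fitting.

Two averaging modes are provided.  ``ensemble-origin`` averages the squared
displacement from the initial position over replicates only; this is the
estimator whose scaling exponent equals the Pareto exponent ν of a
subdiffusive CTRW.  ``time-ensemble`` additionally averages over sliding
time origins within each trajectory; for ergodic processes (Brownian
motion, run-and-tumble at long times) the two agree, but CTRW is weakly
non-ergodic and the time average follows a different scaling law, so
``ensemble-origin`` is the default.

The anomalous exponent α and generalized coefficient K_α are extracted by
ordinary least squares on log MSD vs log lag: log⟨x²⟩ = β₀ + β₁·log t, with
K_α = exp(β₀) and α = β₁.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .trajectory import Trajectory


@dataclass
class MSDCurve:
    """An estimated MSD curve: lags in s, msd in µm²."""

    lags: np.ndarray
    msd: np.ndarray
    n_replicates: int
    dimension: int
    averaging: str = "ensemble-origin"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if len(self.lags) != len(self.msd):
            raise ValueError("lags and msd must have equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be nonnegative")


@dataclass(frozen=True)
class MSDFit:
    """Result of the log–log regression of an MSD curve."""

    K_alpha: float          # exp(intercept), µm²/s^α
    alpha: float            # slope
    alpha_stderr: float
    intercept_stderr: float
    r_squared: float
    fit_window: tuple[float, float]  # lag interval (s) used

    def __post_init__(self) -> None:
        if self.alpha_stderr < 0:
            raise ValueError("alpha_stderr must be >= 0")


def _as_position_array(ensemble) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack a list of same-grid trajectories into (n_rep, n_t, d)."""
    trajs: list[Trajectory] = list(ensemble)
    if len(trajs) < 1:
        raise ValueError("ensemble must contain at least one trajectory")
    t0 = trajs[0].times
    for tr in trajs[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0, rtol=1e-12):
            raise ValueError("all trajectories must share one time grid")
        if tr.dimension != trajs[0].dimension:
            raise ValueError("all trajectories must share one dimension")
    positions = np.stack([tr.positions for tr in trajs])
    return positions, t0, trajs[0].dimension


def ensemble_msd(ensemble, max_lag: int | None = None,
                 averaging: str = "ensemble-origin",
                 dt: float | None = None, dimension: int | None = None) -> MSDCurve:
    """Estimate the ensemble MSD of a trajectory ensemble.

    ``ensemble`` is either a list of :class:`Trajectory` on one time grid or
    a positions array of shape ``(n_rep, n_times, d)`` together with the
    grid spacing ``dt``.  Lags run from 0 to ``max_lag`` grid steps
    (default: all available in ensemble-origin mode, a quarter of the grid
    in time-ensemble mode).
    """
    if averaging not in ("ensemble-origin", "time-ensemble"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    if isinstance(ensemble, np.ndarray):
        if dt is None:
            raise ValueError("dt is required with array input")
        positions = np.asarray(ensemble, dtype=float)
        if positions.ndim != 3:
            raise ValueError("ensemble array must have shape (n_rep, n_times, d)")
        d = positions.shape[2] if dimension is None else dimension
        times = np.arange(positions.shape[1]) * dt
    else:
        positions, times, d = _as_position_array(ensemble)
    n_rep, n_t, _ = positions.shape
    if max_lag is None:
        max_lag = n_t - 1 if averaging == "ensemble-origin" else max(1, (n_t - 1) // 4)
    max_lag = min(max_lag, n_t - 1)

    if averaging == "ensemble-origin":
        disp = positions[:, : max_lag + 1, :] - positions[:, :1, :]
        msd = np.mean(np.sum(disp ** 2, axis=2), axis=0)
    else:
        msd = np.empty(max_lag + 1)
        msd[0] = 0.0
        for k in range(1, max_lag + 1):
            diff = positions[:, k:, :] - positions[:, :-k, :]
            msd[k] = np.mean(np.sum(diff ** 2, axis=2))
    return MSDCurve(lags=times[: max_lag + 1] - times[0], msd=msd,
                    n_replicates=n_rep, dimension=d, averaging=averaging)


def default_fit_window(curve: MSDCurve) -> tuple[float, float]:
    """Default regression window: the last two decades of lag time,
    excluding the first 10 lags (early-time transient)."""
    lags = curve.lags[curve.lags > 0]
    t_max = lags[-1]
    lo = max(t_max / 100.0, lags[min(10, len(lags) - 1)])
    return (lo, t_max)


def fit_msd_loglog(curve: MSDCurve,
                   window: tuple[float, float] | None = None) -> MSDFit:
    """OLS of log(msd) on log(lag) over a lag window.

    Returns K_α = exp(intercept) and α = slope with standard errors and R².
    Lags with zero MSD are dropped with a warning; at least 5 positive
    points must remain.
    """
    if window is None:
        window = default_fit_window(curve)
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0)
    zero = mask & (curve.msd <= 0)
    if np.any(zero):
        warnings.warn(f"dropping {int(zero.sum())} lag(s) with nonpositive MSD "
                      "from the log-log fit", stacklevel=2)
        mask &= curve.msd > 0
    if mask.sum() < 5:
        raise ValueError(f"need >= 5 positive MSD points in window {window}, "
                         f"got {int(mask.sum())}")
    x = np.log(curve.lags[mask])
    y = np.log(curve.msd[mask])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return MSDFit(
        K_alpha=float(np.exp(model.params[0])),
        alpha=float(model.params[1]),
        alpha_stderr=float(model.bse[1]),
        intercept_stderr=float(model.bse[0]),
        r_squared=float(model.rsquared),
        fit_window=(float(lo), float(hi)),
    )
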