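"""Least-squares estimation of the jar heat-transfer rate constant.

Given a bath trace b(t) and jar observations j_i at times t_i, the single
model parameter k is chosen to minimise the residual sum of squares

    RSS(k) = sum_i ( j_i - j(t_i; k, j0) )^2,

with fit quality reported as RMSE = sqrt(RSS / n). The forward predictions
come from the closed-form solver in :mod:`drinksim.heat_transfer`; the
one-dimensional objective is minimised by bounded derivative-free search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .heat_transfer import HeatTransferModel, predict_jar
from .trace import TemperatureTrace

__all__ = ["FitResult", "fit_rate_constant", "rmse_of", "DEFAULT_BOUNDS"]

#: Default search bounds for k, per minute. Brackets jar equilibration time
#: constants from ~6 s to ~17 h, i.e. anything physically plausible for a
#: glass jar in a stirred bath.
DEFAULT_BOUNDS: tuple[float, float] = (1e-3, 10.0)

# k_hat closer than this fraction of the bound span to either bound is
# treated as pinned (the optimum lies at or outside the bracket).
_PIN_FRACTION = 1e-3


@dataclass(frozen=True)
class FitResult:
    """Outcome of a rate-constant fit.

    ``rmse == sqrt(rss / n_obs)`` by construction. ``converged`` is False when
    the estimate is pinned at a search bound (e.g. jar observations that track
    the bath perfectly push k to the upper bound).
    """

    k_hat: float
    rss: float
    rmse: float
    n_obs: int
    j0_used: float
    converged: bool


def _residual_ss(
    k: float, bath: TemperatureTrace, jar_obs: TemperatureTrace, j0: float
) -> float:
    pred = predict_jar(HeatTransferModel(k, j0), bath, jar_obs.times)
    r = jar_obs.temps - pred.temps
    return float(r @ r)


def fit_rate_constant(
    bath: TemperatureTrace,
    jar_obs: TemperatureTrace,
    j0: float | str = "from-data",
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> FitResult:
    """Estimate k by least squares against the forward model.

    Parameters
    ----------
    bath, jar_obs
        Paired logger traces. Jar observation times must start at or after
        the bath trace start (the sampling grids need not match; the bath is
        interpolated).
    j0
        Initial jar temperature. The default ``"from-data"`` uses the first
        jar observation.
    bounds
        Positive (lower, upper) bracket for k in per-minute units.

    The minimisation is deterministic for fixed inputs (bounded Brent,
    absolute tolerance 1e-6 on k).
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be positive with lower < upper")
    if len(jar_obs) < 3:
        raise ValueError("need at least 3 jar observations")
    if jar_obs.times[0] < bath.times[0] - 1e-12 or jar_obs.times[0] > bath.times[-1]:
        raise ValueError("jar observations do not overlap the bath trace span")
    j0_val = float(jar_obs.temps[0]) if isinstance(j0, str) else float(j0)

    res = minimize_scalar(
        _residual_ss,
        bounds=(lo, hi),
        args=(bath, jar_obs, j0_val),
        method="bounded",
        options={"xatol": 1e-6},
    )
    k_hat = float(res.x)
    rss = float(res.fun)
    if not np.isfinite(rss):
        raise FloatingPointError("non-finite least-squares objective")
    n = len(jar_obs)
    pin = _PIN_FRACTION * (hi - lo)
    pinned = (k_hat - lo) < pin or (hi - k_hat) < pin
    return FitResult(
        k_hat=k_hat,
        rss=rss,
        rmse=float(np.sqrt(rss / n)),
        n_obs=n,
        j0_used=j0_val,
        converged=bool(res.success) and not pinned,
    )


def rmse_of(
    model: HeatTransferModel, bath: TemperatureTrace, jar_obs: TemperatureTrace
) -> float:
    """Root mean squared error of jar observations vs the forward model, deg C."""
    rss = _residual_ss(model.rate_constant, bath, jar_obs, model.initial_jar_temp)
    return float(np.sqrt(rss / len(jar_obs)))
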