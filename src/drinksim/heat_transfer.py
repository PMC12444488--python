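"""Forced Newton cooling/heating of a fermentation jar in a water bath.

The jar temperature j(t) responds to the (experimentally controlled) bath
temperature b(t) through

    dj/dt = -k [ j(t) - b(t) ],        k > 0  (per minute),

whose integrating-factor solution is

    j(t) = exp(-k t) [ j0 + k * integral_0^t b(u) exp(k u) du ].

The bath trace is known only at logger samples; between samples it is taken
as piecewise linear. On each linear segment b(u) = b_i + beta (u - t_i) the
ODE has the exact solution

    j(t) = b(t) - beta/k + (j(t_i) - b_i + beta/k) exp(-k (t - t_i)),

so :func:`predict_jar` propagates the state segment-by-segment in closed
form. Only decaying exponentials appear, so the computation is stable for
any k and trace length (no exp(k t) overflow). A fixed-step Runge-Kutta
integrator (:func:`ode_oracle`) is provided purely as an independent
cross-check for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from .trace import TemperatureTrace

__all__ = [
    "HeatTransferModel",
    "bath_function",
    "predict_jar",
    "ode_oracle",
    "jar_minimum",
]


@dataclass(frozen=True)
class HeatTransferModel:
    """Jar response parameters: rate constant k (per minute) and j(0)."""

    rate_constant: float
    initial_jar_temp: float

    def __post_init__(self) -> None:
        if not self.rate_constant > 0:
            raise ValueError("rate_constant must be positive")
        if not np.isfinite(self.initial_jar_temp):
            raise ValueError("initial_jar_temp must be finite")


def bath_function(trace: TemperatureTrace) -> Callable[[float], float]:
    """Continuous bath temperature: linear between samples, constant outside.

    Returns a vectorised callable t (minutes) -> deg C.
    """
    if len(trace) < 2:
        raise ValueError("bath trace needs at least 2 points")
    t, y = trace.times, trace.temps

    def b(u):
        return np.interp(u, t, y)

    return b


def _jar_at_knots(k: float, j0: float, times: np.ndarray, temps: np.ndarray) -> np.ndarray:
    """Exact jar temperatures at the bath sample times.

    Propagates the affine recurrence j_{i+1} = c_i + E_i j_i with
    E_i = exp(-k dt_i). On a uniform grid E is a scalar and the recurrence is
    a first-order IIR filter, evaluated with scipy's lfilter.
    """
    dt = np.diff(times)
    beta = np.diff(temps) / dt
    g = beta / k
    E = np.exp(-k * dt)
    c = temps[1:] - g - E * (temps[:-1] - g)
    out = np.empty_like(temps)
    out[0] = j0
    if dt.size and np.ptp(dt) <= 1e-12 * dt[0]:
        e = float(E[0])
        y, _ = lfilter([1.0], [1.0, -e], c, zi=np.array([e * j0]))
        out[1:] = y
    else:
        acc = j0
        for i in range(dt.size):
            acc = c[i] + E[i] * acc
            out[i + 1] = acc
    return out


def predict_jar(
    model: HeatTransferModel,
    bath: TemperatureTrace,
    eval_times: Sequence[float],
) -> TemperatureTrace:
    """Jar temperature under the forced Newton model, exactly, at ``eval_times``.

    ``eval_times`` must be at or after the first bath sample; beyond the last
    bath sample the bath is held at its final value. j(0) is taken at the
    first bath sample time.
    """
    t = np.asarray(eval_times, dtype=float)
    knots, b = bath.times, bath.temps
    k, j0 = model.rate_constant, model.initial_jar_temp
    if t.size == 0:
        raise ValueError("eval_times must be non-empty")
    if np.any(t < knots[0] - 1e-12):
        raise ValueError("eval_times must not precede the bath trace start")

    jk = _jar_at_knots(k, j0, knots, b)
    dt = np.diff(knots)
    beta = np.diff(b) / dt
    g = beta / k

    idx = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, knots.size - 2)
    s = t - knots[idx]
    j = (b[idx] + beta[idx] * s) - g[idx] + (jk[idx] - b[idx] + g[idx]) * np.exp(-k * s)

    beyond = t > knots[-1]
    if np.any(beyond):  # constant-bath tail
        s2 = t[beyond] - knots[-1]
        j[beyond] = b[-1] + (jk[-1] - b[-1]) * np.exp(-k * s2)
    if not np.all(np.isfinite(j)):
        raise FloatingPointError("non-finite jar prediction")
    return TemperatureTrace(t, j, label="jar (predicted)")


def ode_oracle(
    model: HeatTransferModel,
    bath: TemperatureTrace,
    eval_times: Sequence[float],
    step: float = 0.01,
) -> TemperatureTrace:
    """Classic fixed-step RK4 integration of dj/dt = -k (j - b(t)).

    Testing oracle only: independent of the closed-form production path.
    ``step`` (minutes) must not exceed half the shortest bath segment so the
    interpolant's slope breaks are resolved.
    """
    t_eval = np.asarray(eval_times, dtype=float)
    if np.any(t_eval < bath.times[0] - 1e-12):
        raise ValueError("eval_times must not precede the bath trace start")
    min_seg = float(np.min(np.diff(bath.times)))
    if step > min_seg / 2:
        raise ValueError(
            f"step {step} min exceeds half the smallest bath segment ({min_seg} min)"
        )
    b = bath_function(bath)
    k = model.rate_constant
    t0 = float(bath.times[0])
    t_end = max(float(np.max(t_eval)), t0 + step)
    # align steps with the interpolant's slope breaks and with the requested
    # output times, so no RK4 step straddles a knot and no output value needs
    # interpolation off the dense solution
    edges = np.unique(np.concatenate([bath.times, t_eval, [t_end]]))
    edges = edges[(edges >= t0) & (edges <= t_end)]
    pieces = [np.array([t0])]
    for a, bnd in zip(edges[:-1], edges[1:]):
        m = max(1, int(np.ceil((bnd - a) / step)))
        pieces.append(a + (bnd - a) * np.arange(1, m + 1) / m)
    grid = np.concatenate(pieces)

    def f(t, j):
        return -k * (j - b(t))

    j = np.empty_like(grid)
    j[0] = model.initial_jar_temp
    for i in range(grid.size - 1):
        t = grid[i]
        h = grid[i + 1] - t
        y = j[i]
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h * k1 / 2)
        k3 = f(t + h / 2, y + h * k2 / 2)
        k4 = f(t + h, y + h * k3)
        j[i + 1] = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
    out = np.interp(t_eval, grid, j)
    return TemperatureTrace(t_eval, out, label="jar (RK4)")


def jar_minimum(trace: TemperatureTrace) -> tuple[float, float]:
    """Earliest global minimum of a trace: (time minutes, temperature deg C)."""
    i = int(np.argmin(trace.temps))
    return float(trace.times[i]), float(trace.temps[i])
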