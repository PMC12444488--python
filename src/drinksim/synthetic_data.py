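"""Synthetic bath/jar logger traces and the logger CSV dialect.

Real episode recordings come from small autonomous temperature loggers
(3-second sampling, Gaussian sensor noise, and coarse quantization — typical
iButton resolutions run from 0.5 down to 0.0625 degC). This module layers
that sensor model on top of the ideal episode trajectories from
:mod:`drinksim.event_design`, and reads/writes the canonical logger CSV
dialect (``elapsed_s,temp_C``).

All stochastic output is deterministic given the configured seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .event_design import EventPlan, ideal_bath_trace
from .heat_transfer import HeatTransferModel, predict_jar
from .trace import TemperatureTrace

__all__ = [
    "LoggerConfig",
    "generate_bath_trace",
    "generate_jar_obs",
    "read_logger_csv",
    "write_logger_csv",
]


@dataclass(frozen=True)
class LoggerConfig:
    """Data-logger sensor model.

    sampling_interval is in seconds (default 3 s); noise_sd is the Gaussian
    sensor noise in degC; quantization is the logger resolution in degC
    (0 disables it; hardware resolutions run 0.0625-0.5 degC).
    """

    sampling_interval: float = 3.0
    noise_sd: float = 0.05
    quantization: float = 0.0625
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.quantization != 0 and not 0.0625 <= self.quantization <= 0.5:
            raise ValueError("quantization must be 0 (off) or in [0.0625, 0.5] degC")

    @property
    def interval_minutes(self) -> float:
        return self.sampling_interval / 60.0


def _apply_sensor(temps: np.ndarray, config: LoggerConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    out = temps + rng.normal(0.0, config.noise_sd, size=temps.shape)
    if config.quantization:
        # round-to-nearest on the absolute Celsius scale, ties to even
        out = np.round(out / config.quantization) * config.quantization
    return out


def generate_bath_trace(
    plan: EventPlan,
    mixing_tau: float = 0.5,
    stage_dwell: float = 3.0,
    config: LoggerConfig = LoggerConfig(),
    pre_hold: float = 10.0,
    post_hold: float = 0.0,
) -> TemperatureTrace:
    """Logger-like bath recording of the planned episode(s).

    The underlying trajectory is the ideal one (baseline hold, first-order
    mixing transient per stage, recovery ramp); sensor noise and quantization
    are applied last.
    """
    ideal = ideal_bath_trace(
        plan,
        mixing_tau=mixing_tau,
        stage_dwell=stage_dwell,
        sampling_interval=config.interval_minutes,
        pre_hold=pre_hold,
        post_hold=post_hold,
    )
    return TemperatureTrace(ideal.times, _apply_sensor(ideal.temps, config), "bath")


def generate_jar_obs(
    model: HeatTransferModel,
    bath: TemperatureTrace,
    config: LoggerConfig = LoggerConfig(),
) -> TemperatureTrace:
    """Logger-like jar recording: forward model + sensor model.

    The forward model is evaluated at the logger sampling grid spanning the
    bath trace; noise and quantization are applied last.
    """
    dt = config.interval_minutes
    t0, t1 = float(bath.times[0]), float(bath.times[-1])
    n = int(np.floor((t1 - t0) / dt + 1e-9))
    times = t0 + np.arange(n + 1) * dt
    pred = predict_jar(model, bath, times)
    return TemperatureTrace(times, _apply_sensor(pred.temps, config), "jar")


# ---------------------------------------------------------------------------
# Logger CSV dialect: elapsed_s,temp_C with header; '#' comment lines allowed
# ---------------------------------------------------------------------------


def write_logger_csv(trace: TemperatureTrace, path: str | Path) -> None:
    """Write a trace as ``elapsed_s,temp_C`` rows (times converted to seconds)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["elapsed_s", "temp_C"])
        for t, y in zip(trace.times, trace.temps):
            writer.writerow([repr(float(t) * 60.0), repr(float(y))])


def read_logger_csv(path: str | Path, label: str = "") -> TemperatureTrace:
    """Read a logger CSV; returns a trace with times in minutes.

    Skips ``#`` comment lines; rejects a missing/incorrect header, unparseable
    rows, and non-monotone time stamps, naming the offending line.
    """
    times_s: list[float] = []
    temps: list[float] = []
    header = None
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                if header != ["elapsed_s", "temp_C"]:
                    raise ValueError(
                        f"line {lineno}: expected header 'elapsed_s,temp_C', "
                        f"got {','.join(header)!r}"
                    )
                continue
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 fields, got {len(fields)}")
            try:
                t = float(fields[0])
                y = float(fields[1])
            except ValueError as err:
                raise ValueError(f"line {lineno}: unparseable row {line!r}") from err
            if times_s and t <= times_s[-1]:
                raise ValueError(
                    f"line {lineno}: elapsed_s {t!r} is not strictly increasing"
                )
            times_s.append(t)
            temps.append(y)
    if header is None:
        raise ValueError("logger file is empty or has no header")
    if len(times_s) < 2:
        raise ValueError("logger file needs at least 2 data rows")
    return TemperatureTrace(np.asarray(times_s) / 60.0, np.asarray(temps), label)
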