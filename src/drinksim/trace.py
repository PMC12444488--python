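"""Time-temperature traces, the common currency of bath and jar loggers.

A :class:`TemperatureTrace` holds an ordered series of (time, temperature)
observations. Times are elapsed **minutes** from the first logger sample;
temperatures are degrees Celsius. Sampling may be irregular, though traces
produced by the generator use a uniform 3-s (0.05 min) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemperatureTrace"]


@dataclass(frozen=True)
class TemperatureTrace:
    """Ordered (time, temperature) observations from a single sensor.

    Parameters
    ----------
    times : array-like
        Elapsed minutes from the trace start; strictly increasing, >= 0.
    temps : array-like
        Temperatures in deg C, same length as ``times``, all finite.
    label : str
        Free-text tag, e.g. ``"bath"`` or ``"jar"``.

    Logger recordings always carry at least two samples (readers and the
    interpolation/fitting routines enforce this); single-point traces are
    permitted only as model-evaluation output.
    """

    times: np.ndarray
    temps: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.temps, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and temps must be 1-D arrays of equal length")
        if t.size < 1:
            raise ValueError("a trace needs at least one observation")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("times and temperatures must be finite")
        if t[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        t.flags.writeable = False
        y.flags.writeable = False
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temps", y)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Trace span in minutes."""
        return float(self.times[-1] - self.times[0])

    def with_label(self, label: str) -> "TemperatureTrace":
        return TemperatureTrace(self.times, self.temps, label)
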