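"""Design and detection of full drinking-event episodes.

A drinking event, as seen by a fermentation jar standing in a water bath, is:
a baseline hold at 39 degC, a rapid bath drop caused by adding cold water
(sized by the mixture law), and a programmed recovery ramp executed by the
heating circulator, which activates once the bath reaches the profile's
anchor temperature (tolerance +/- 0.01 degC). The jar responds through the
forced Newton model, so its drop is attenuated and lagged relative to the
bath's.

This module builds such episodes (:func:`plan_event`, :func:`simulate_event`),
answers the inverse design question "how deep must the bath drop so the jar
drops by the target amount" (:func:`required_bath_drop_for_jar_drop`), and
measures recovery periods in observed or simulated traces
(:func:`recovery_period`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .heat_transfer import HeatTransferModel, predict_jar
from .thermo import required_cold_volume
from .trace import TemperatureTrace

__all__ = [
    "ACTIVATION_TOLERANCE",
    "InfeasibleDesignError",
    "NotRecoveredError",
    "RampProfile",
    "DrinkingEventSpec",
    "EventPlan",
    "default_recovery_profile",
    "profile_to_setpoints",
    "required_bath_drop_for_jar_drop",
    "plan_event",
    "protocol_plan",
    "ideal_bath_trace",
    "simulate_event",
    "recovery_period",
    "read_profile_csv",
    "write_profile_csv",
]

#: The circulator starts its ramp at the first sample within this band of the
#: profile anchor temperature (degC).
ACTIVATION_TOLERANCE = 0.01

#: Recovery threshold modes: return to within 0.10 degC of baseline, or to
#: 90% / 99% of the dropped temperature.
RECOVERY_MODES = ("abs_0.10C", "pct90", "pct99")


class InfeasibleDesignError(ValueError):
    """The requested event cannot be realised; the message names the binding
    constraint."""


class NotRecoveredError(RuntimeError):
    """The trace never met the recovery criterion; carries the closing deficit."""

    def __init__(self, deficit: float):
        self.deficit = float(deficit)
        super().__init__(
            f"recovery criterion not met within the trace "
            f"(still {self.deficit:.3f} degC short at the last sample)"
        )


# ---------------------------------------------------------------------------
# Ramp profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RampProfile:
    """Circulator setpoint ramp: ordered (target degC, duration minutes) steps.

    The ramp is armed while the bath is falling and starts at the first
    sample within ``ACTIVATION_TOLERANCE`` of ``activation_temp``. A leading
    zero-duration step is allowed as an anchor row; all other durations must
    be positive.
    """

    activation_temp: float
    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(d)) for t, d in self.segments)
        if not segs:
            raise ValueError("profile needs at least one segment")
        for i, (_, dur) in enumerate(segs):
            if dur < 0 or (dur == 0 and i != 0):
                raise ValueError(
                    "segment durations must be positive (a zero-duration "
                    "anchor is allowed only as the first step)"
                )
        if sum(d for _, d in segs) <= 0:
            raise ValueError("profile has no ramp time")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        """Summed segment durations, minutes."""
        return float(sum(d for _, d in self.segments))

    @property
    def final_target(self) -> float:
        return float(self.segments[-1][0])


def default_recovery_profile() -> RampProfile:
    """The standard 2-hour recovery ramp for a 39 degC baseline episode.

    Anchored at 27 degC, then 27 -> 36 in 30 min, 36 -> 38 in 30 min,
    38 -> 39 in 60 min: 120 min of ramp in total.
    """
    return RampProfile(
        activation_temp=27.0,
        segments=((27.0, 0.0), (36.0, 30.0), (38.0, 30.0), (39.0, 60.0)),
    )


def _profile_knots(profile: RampProfile) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear knot times/temps of the setpoint ramp (t=0 at activation)."""
    kt, kT = [0.0], [float(profile.activation_temp)]
    cur = 0.0
    for target, dur in profile.segments:
        if dur == 0.0:
            kT[-1] = target  # anchor overrides the start temperature
        else:
            cur += dur
            kt.append(cur)
            kT.append(target)
    return np.asarray(kt), np.asarray(kT)


def profile_to_setpoints(profile: RampProfile, sampling_interval: float) -> TemperatureTrace:
    """Realise the circulator's piecewise-linear ramp as a sampled trace.

    Knot times and temperatures are represented exactly (the regular sampling
    grid is augmented with the knots).
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    kt, kT = _profile_knots(profile)
    grid = np.arange(0.0, kt[-1], sampling_interval)
    times = np.unique(np.concatenate([grid, kt]))
    return TemperatureTrace(times, np.interp(times, kt, kT), label="setpoints")


def _reanchored_profile(
    baseline: float, bath_drop: float, recovery_duration: float = 120.0
) -> RampProfile:
    """The standard ramp shape re-anchored at ``baseline - bath_drop``.

    Intermediate targets keep their position relative to a 39 degC baseline
    (shifted for other baselines) but are clipped to the anchor so the ramp
    never descends; durations scale with the requested recovery length.
    """
    anchor = round(baseline - bath_drop, 2)
    shift = baseline - 39.0
    scale = recovery_duration / 120.0
    base_steps = ((36.0, 30.0), (38.0, 30.0), (39.0, 60.0))
    segs = [(anchor, 0.0)]
    segs += [(max(t + shift, anchor), d * scale) for t, d in base_steps]
    return RampProfile(activation_temp=anchor, segments=tuple(segs))


# ---------------------------------------------------------------------------
# Event specification and plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrinkingEventSpec:
    """Design parameters of a drinking-event episode.

    Defaults describe the reference protocol: a 12.5 L bath at 39 degC in a
    20 L tray, 4 degC cold water, a 9 degC target drop in the jar, and a
    120-min recovery.
    """

    baseline_temp: float = 39.0
    target_jar_drop: float = 9.0
    recovery_duration: float = 120.0
    bath_volume: float = 12.5
    bath_capacity: float = 20.0
    cold_water_temp: float = 4.0
    n_iterations: int = 1
    recovery_threshold_mode: str = "pct99"

    def __post_init__(self) -> None:
        if not 0 < self.target_jar_drop < self.baseline_temp - self.cold_water_temp:
            raise ValueError(
                "target_jar_drop must be positive and below "
                "baseline_temp - cold_water_temp"
            )
        if not self.bath_volume < self.bath_capacity:
            raise ValueError("bath_volume must be below bath_capacity")
        if self.recovery_duration <= 0:
            raise ValueError("recovery_duration must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.recovery_threshold_mode not in RECOVERY_MODES:
            raise ValueError(f"recovery_threshold_mode must be one of {RECOVERY_MODES}")


@dataclass(frozen=True)
class EventPlan:
    """A fully resolved episode protocol.

    ``stage_volumes`` are the successive cold-water additions (litres);
    ``removed_volume`` is mixed bath water shifted out before the final
    addition to respect the tray capacity. ``expected_bath_drop`` and
    ``expected_jar_drop`` are the drops the plan is designed to realise.
    """

    cold_volume: float
    staged: bool
    stage_volumes: tuple[float, ...]
    removed_volume: float
    expected_bath_drop: float
    expected_jar_drop: float
    profile: RampProfile
    spec: DrinkingEventSpec

    def __post_init__(self) -> None:
        if abs(sum(self.stage_volumes) - self.cold_volume) > 1e-9 * max(
            1.0, self.cold_volume
        ):
            raise ValueError("stage volumes must sum to cold_volume")
        if self.removed_volume < 0:
            raise ValueError("removed_volume cannot be negative")
        final = self.spec.bath_volume + self.cold_volume - self.removed_volume
        if final > self.spec.bath_capacity + 1e-9:
            raise ValueError("plan exceeds bath capacity")
        if self.expected_jar_drop > self.expected_bath_drop + 1e-9:
            raise ValueError("jar drop cannot exceed bath drop (attenuation)")


def protocol_plan(spec: DrinkingEventSpec | None = None) -> EventPlan:
    """The reference laboratory protocol as an :class:`EventPlan`.

    7.0 L of 4 degC water added in two stages (4.5 L, then 2.5 L after
    shifting 3.5 L of mixed bath water out), with the standard 27-degC-anchored
    recovery ramp. The ramp catches the falling bath at its 27 degC anchor,
    giving a nominal 12 degC bath drop and around a 9 degC jar drop.
    """
    spec = spec or DrinkingEventSpec()
    return EventPlan(
        cold_volume=7.0,
        staged=True,
        stage_volumes=(4.5, 2.5),
        removed_volume=3.5,
        expected_bath_drop=spec.baseline_temp - 27.0,
        expected_jar_drop=spec.target_jar_drop,
        profile=default_recovery_profile(),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Addition sizing (mixture chain)
# ---------------------------------------------------------------------------


def _stage_equilibria(
    spec: DrinkingEventSpec,
    stage_volumes: Sequence[float],
    removed_volume: float,
) -> list[float]:
    """Bath equilibrium temperature after each staged addition.

    Water removed to make room leaves at the current mixed temperature (no
    temperature change) immediately before the final addition.
    """
    mass = spec.bath_volume
    temp = spec.baseline_temp
    cold = spec.cold_water_temp
    out = []
    for i, v in enumerate(stage_volumes):
        if i == len(stage_volumes) - 1 and removed_volume > 0:
            mass -= removed_volume
            if mass <= 0:
                raise InfeasibleDesignError("removed more water than the bath holds")
        temp = (mass * temp + v * cold) / (mass + v)
        mass += v
        out.append(temp)
    return out


def _size_addition(
    spec: DrinkingEventSpec, bath_drop: float
) -> tuple[float, tuple[float, ...], float]:
    """Cold volume, stage split and removed volume realising a bath drop.

    Single addition when it fits the tray; otherwise stage 1 fills the tray
    to capacity and the balance is added after shifting the same volume of
    mixed water out. Because removal discards warm mixed water, the staged
    total is found by solving the staged mixture chain (it reduces to the
    plain mixture inversion in the single-stage case).
    """
    target = spec.baseline_temp - bath_drop
    if target <= spec.cold_water_temp + 1e-9:
        raise InfeasibleDesignError(
            f"a {bath_drop:.2f} degC bath drop needs a final temperature of "
            f"{target:.2f} degC, not reachable with cold water at "
            f"{spec.cold_water_temp:.2f} degC"
        )
    v_single = required_cold_volume(
        spec.bath_volume, spec.baseline_temp, spec.cold_water_temp, target
    )
    if spec.bath_volume + v_single <= spec.bath_capacity + 1e-12:
        return v_single, (v_single,), 0.0

    s1 = spec.bath_capacity - spec.bath_volume

    def chain_gap(total: float) -> float:
        stages = (s1, total - s1)
        final = _stage_equilibria(spec, stages, removed_volume=total - s1)[-1]
        return final - target

    lo = s1 * (1 + 1e-9) + 1e-9
    hi = s1 + (spec.bath_volume + s1) * (1 - 1e-9)
    total = float(brentq(chain_gap, lo, hi, xtol=1e-10))
    return total, (s1, total - s1), total - s1


# ---------------------------------------------------------------------------
# Ideal bath trajectory
# ---------------------------------------------------------------------------


def ideal_bath_trace(
    plan: EventPlan,
    mixing_tau: float = 0.5,
    stage_dwell: float = 3.0,
    sampling_interval: float = 0.05,
    pre_hold: float = 10.0,
    post_hold: float = 0.0,
) -> TemperatureTrace:
    """Noise-free bath trajectory of the planned episode(s) on a uniform grid.

    Each episode is: a baseline hold (``pre_hold`` minutes), then per stage a
    first-order approach to that stage's mixture equilibrium with time
    constant ``mixing_tau`` (0 = instantaneous step), with ``stage_dwell``
    minutes between stages; the recovery ramp starts at the first sample
    within ``ACTIVATION_TOLERANCE`` of the profile anchor. For
    ``spec.n_iterations > 1`` episodes concatenate back to back.
    """
    if mixing_tau < 0 or stage_dwell < 0 or sampling_interval <= 0:
        raise ValueError("mixing_tau/stage_dwell must be >= 0, sampling_interval > 0")
    spec = plan.spec
    dt = sampling_interval
    base = spec.baseline_temp
    act = plan.profile.activation_temp
    trigger = act + ACTIVATION_TOLERANCE
    eqs = _stage_equilibria(spec, plan.stage_volumes, plan.removed_volume)

    temps: list[float] = [base] * max(1, round(pre_hold / dt))
    cur = base
    for i, teq in enumerate(eqs):
        last = i == len(eqs) - 1
        if last:
            if teq > trigger + 1e-9:
                raise InfeasibleDesignError(
                    f"mixture equilibrium {teq:.2f} degC never reaches the "
                    f"profile anchor {act:.2f} degC; the ramp would not activate"
                )
            if mixing_tau == 0 or cur <= trigger:
                m = 1
                vals = np.array([teq if mixing_tau == 0 else cur])
            else:
                gap0 = cur - teq
                gap_target = trigger - teq
                if gap_target <= 0:
                    raise InfeasibleDesignError(
                        "activation temperature coincides with the mixture "
                        "equilibrium; the bath only reaches it asymptotically"
                    )
                m = max(1, math.ceil(mixing_tau / dt * math.log(gap0 / gap_target)))
                j = np.arange(1, m + 1)
                vals = teq + gap0 * np.exp(-j * dt / mixing_tau)
        else:
            m = max(1, round(stage_dwell / dt))
            j = np.arange(1, m + 1)
            if mixing_tau == 0:
                vals = np.full(m, teq)
            else:
                vals = teq + (cur - teq) * np.exp(-j * dt / mixing_tau)
        temps.extend(vals.tolist())
        cur = float(vals[-1])

    kt, kT = _profile_knots(plan.profile)
    n_ramp = max(1, round(kt[-1] / dt))
    ramp = np.interp(np.arange(1, n_ramp + 1) * dt, kt, kT)
    temps.extend(ramp.tolist())
    temps.extend([base] * round(post_hold / dt))

    episode = np.asarray(temps)
    full = np.tile(episode, spec.n_iterations)
    return TemperatureTrace(np.arange(full.size) * dt, full, label="bath (ideal)")


# ---------------------------------------------------------------------------
# Inverse design
# ---------------------------------------------------------------------------


def _jar_excursion(
    bath: TemperatureTrace, rate_constant: float, baseline: float
) -> float:
    """Maximum jar excursion below baseline for a jar starting at baseline."""
    jar = predict_jar(HeatTransferModel(rate_constant, baseline), bath, bath.times)
    return baseline - float(np.min(jar.temps))


def _instant_drop_bath(
    spec: DrinkingEventSpec, bath_drop: float, sampling_interval: float, pre_hold: float
) -> TemperatureTrace:
    """Idealised episode bath: instantaneous drop, then the re-anchored ramp."""
    dt = sampling_interval
    profile = _reanchored_profile(spec.baseline_temp, bath_drop, spec.recovery_duration)
    kt, kT = _profile_knots(profile)
    n_hold = max(1, round(pre_hold / dt))
    n_ramp = max(1, round(kt[-1] / dt))
    temps = np.concatenate(
        [np.full(n_hold, spec.baseline_temp), np.interp(np.arange(n_ramp + 1) * dt, kt, kT)]
    )
    return TemperatureTrace(np.arange(temps.size) * dt, temps, label="bath (design)")


def required_bath_drop_for_jar_drop(
    model: HeatTransferModel,
    spec: DrinkingEventSpec,
    tol: float = 0.01,
    sampling_interval: float = 0.05,
    pre_hold: float = 10.0,
) -> float:
    """Smallest bath drop whose episode pulls the jar down by the target.

    The candidate bath drops instantaneously by ``d`` and immediately follows
    the recovery ramp re-anchored at ``baseline - d``; the jar excursion is
    evaluated with the forward model and ``d`` is located by bisection to
    ``tol`` degC. The result is always >= the target jar drop (attenuation).
    """
    target = spec.target_jar_drop
    base = spec.baseline_temp

    def excursion(d: float) -> float:
        bath = _instant_drop_bath(spec, d, sampling_interval, pre_hold)
        return _jar_excursion(bath, model.rate_constant, base)

    lo = target
    hi = base - spec.cold_water_temp - 0.05
    if excursion(hi) < target:
        raise InfeasibleDesignError(
            f"even a {hi:.2f} degC bath drop (the deepest reachable with "
            f"{spec.cold_water_temp:.1f} degC water) leaves the jar short of a "
            f"{target:.2f} degC drop; colder water or a longer low phase is needed"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excursion(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def plan_event(
    spec: DrinkingEventSpec,
    model: HeatTransferModel,
    mixing_tau: float = 0.5,
    stage_dwell: float = 3.0,
    sampling_interval: float = 0.05,
    pre_hold: float = 10.0,
    tol: float = 0.01,
) -> EventPlan:
    """Resolve a full episode protocol meeting the spec's target jar drop.

    Bisects on the bath drop, at each candidate sizing the cold addition
    through the mixture chain (staging when the tray would overflow) and
    forward-simulating the same transient bath trajectory that
    :func:`simulate_event` produces, so the designed and simulated jar drops
    agree to within the bisection tolerance.
    """
    base = spec.baseline_temp
    target = spec.target_jar_drop
    search_spec = replace(spec, n_iterations=1)

    def candidate(d: float) -> EventPlan:
        total, stages, removed = _size_addition(spec, d)
        profile = _reanchored_profile(base, d, spec.recovery_duration)
        return EventPlan(
            cold_volume=total,
            staged=len(stages) > 1,
            stage_volumes=stages,
            removed_volume=removed,
            expected_bath_drop=d,
            expected_jar_drop=min(d, target),
            profile=profile,
            spec=search_spec,
        )

    def excursion(d: float) -> float:
        bath = ideal_bath_trace(
            candidate(d), mixing_tau, stage_dwell, sampling_interval, pre_hold
        )
        return _jar_excursion(bath, model.rate_constant, base)

    lo = target
    hi = base - spec.cold_water_temp - 0.1
    if excursion(hi) < target:
        raise InfeasibleDesignError(
            f"target jar drop {target:.2f} degC unreachable with "
            f"{spec.cold_water_temp:.1f} degC cold water even at the deepest "
            f"feasible bath drop ({hi:.2f} degC)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excursion(mid) >= target:
            hi = mid
        else:
            lo = mid

    # the trigger sample can sit a hair below the anchor, so the measured
    # excursion may exceed the nominal bath drop by < tol; clamp to keep the
    # attenuation contract exact
    achieved = min(excursion(hi), hi)
    final = candidate(hi)
    return replace(final, expected_jar_drop=achieved, spec=spec)


def simulate_event(
    plan: EventPlan,
    model: HeatTransferModel,
    sampling_interval: float = 0.05,
    mixing_tau: float = 0.5,
    stage_dwell: float = 3.0,
    pre_hold: float = 10.0,
    post_hold: float = 0.0,
) -> tuple[TemperatureTrace, TemperatureTrace]:
    """Forward-simulate the planned episode(s): (bath, jar) traces.

    The jar starts at the episode baseline and follows the forced Newton
    model over the full bath trajectory; episodes concatenate when the spec
    asks for several iterations.
    """
    bath = ideal_bath_trace(
        plan, mixing_tau, stage_dwell, sampling_interval, pre_hold, post_hold
    )
    jar_model = HeatTransferModel(model.rate_constant, plan.spec.baseline_temp)
    jar = predict_jar(jar_model, bath, bath.times).with_label("jar (simulated)")
    return bath, jar


# ---------------------------------------------------------------------------
# Recovery detection
# ---------------------------------------------------------------------------


def recovery_period(
    trace: TemperatureTrace, baseline: float, mode: str = "pct99"
) -> float:
    """Minutes from the trace minimum to the first sample meeting the criterion.

    Modes: ``abs_0.10C`` (within 0.10 degC of baseline), ``pct90`` / ``pct99``
    (90% / 99% of the dropped temperature recovered). Raises ``ValueError``
    when the trace never dips below baseline and :class:`NotRecoveredError`
    when the criterion is never met after the minimum.
    """
    if mode not in RECOVERY_MODES:
        raise ValueError(f"mode must be one of {RECOVERY_MODES}")
    imin = int(np.argmin(trace.temps))
    tmin = float(trace.temps[imin])
    if tmin >= baseline:
        raise ValueError("trace has no minimum below baseline")
    if mode == "abs_0.10C":
        threshold = baseline - 0.10
    else:
        frac = 0.90 if mode == "pct90" else 0.99
        threshold = tmin + frac * (baseline - tmin)
    after = trace.temps[imin:]
    hits = np.nonzero(after >= threshold)[0]
    if hits.size == 0:
        raise NotRecoveredError(threshold - float(trace.temps[-1]))
    return float(trace.times[imin + hits[0]] - trace.times[imin])


# ---------------------------------------------------------------------------
# Profile file I/O (target_C,duration rows; duration as hh:mm:ss)
# ---------------------------------------------------------------------------


def _format_duration(minutes: float) -> str:
    total = round(minutes * 60)
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _parse_duration(text: str, lineno: int) -> float:
    parts = text.strip().split(":")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        raise ValueError(f"line {lineno}: duration {text!r} is not hh:mm:ss")
    h, m, s = (int(p) for p in parts)
    if m >= 60 or s >= 60:
        raise ValueError(f"line {lineno}: duration {text!r} has minutes/seconds >= 60")
    return h * 60 + m + s / 60


def write_profile_csv(profile: RampProfile, path: str | Path) -> None:
    """Write a ramp profile as ``target_C,duration`` rows (duration hh:mm:ss).

    The anchor appears as a leading zero-duration row, mirroring circulator
    programming templates.
    """
    rows = list(profile.segments)
    if rows[0][1] != 0.0:
        rows.insert(0, (profile.activation_temp, 0.0))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_C", "duration"])
        for target, dur in rows:
            writer.writerow([f"{target:.2f}", _format_duration(dur)])


def read_profile_csv(path: str | Path) -> RampProfile:
    """Read a ramp profile written by :func:`write_profile_csv`.

    The first data row must be the zero-duration anchor (it defines the
    activation temperature). Lines starting with ``#`` are skipped; parse
    failures report the offending line number.
    """
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                if header != ["target_C", "duration"]:
                    raise ValueError(
                        f"line {lineno}: expected header 'target_C,duration', "
                        f"got {','.join(header)!r}"
                    )
                continue
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 fields, got {len(fields)}")
            try:
                target = float(fields[0])
            except ValueError as err:
                raise ValueError(
                    f"line {lineno}: unparseable temperature {fields[0]!r}"
                ) from err
            rows.append((target, _parse_duration(fields[1], lineno)))
    if header is None:
        raise ValueError("profile file is empty or has no header")
    if not rows:
        raise ValueError("profile file has no data rows")
    if rows[0][1] != 0.0:
        raise ValueError(
            "first data row must be the zero-duration anchor (duration 00:00:00)"
        )
    return RampProfile(activation_temp=rows[0][0], segments=tuple(rows))
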