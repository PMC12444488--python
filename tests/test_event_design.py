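"""Episode construction: profiles, inverse design, planning, recovery."""

from dataclasses import replace

import numpy as np
import pytest

import drinksim as ds
from drinksim import (
    DrinkingEventSpec,
    EventPlan,
    HeatTransferModel,
    InfeasibleDesignError,
    NotRecoveredError,
    RampProfile,
    TemperatureTrace,
    default_recovery_profile,
    jar_minimum,
    plan_event,
    profile_to_setpoints,
    read_profile_csv,
    recovery_period,
    required_bath_drop_for_jar_drop,
    simulate_event,
    write_profile_csv,
)
from drinksim.event_design import _instant_drop_bath, _jar_excursion


class TestRecoveryProfile:
    def test_default_profile_shape(self):
        p = default_recovery_profile()
        assert p.activation_temp == 27.0
        assert p.segments[0] == (27.0, 0.0)  # zero-duration anchor
        assert p.total_duration == 120.0
        assert p.final_target == 39.0

    def test_zero_duration_only_allowed_as_anchor(self):
        with pytest.raises(ValueError):
            RampProfile(27.0, ((27.0, 0.0), (36.0, 0.0), (39.0, 60.0)))
        with pytest.raises(ValueError):
            RampProfile(27.0, ())

    @pytest.mark.parametrize("t, expected", [(15.0, 31.5), (60.0, 38.0), (120.0, 39.0)])
    def test_setpoint_ramp_values(self, t, expected):
        sp = profile_to_setpoints(default_recovery_profile(), 0.05)
        assert np.interp(t, sp.times, sp.temps) == pytest.approx(expected, abs=1e-12)

    def test_setpoint_knots_are_exact(self):
        sp = profile_to_setpoints(default_recovery_profile(), 0.07)  # grid misses knots
        for knot_t, knot_T in [(0.0, 27.0), (30.0, 36.0), (60.0, 38.0), (120.0, 39.0)]:
            i = np.searchsorted(sp.times, knot_t)
            assert sp.times[i] == knot_t and sp.temps[i] == knot_T

    def test_profile_csv_round_trip(self, tmp_path):
        path = tmp_path / "profile.csv"
        write_profile_csv(default_recovery_profile(), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "target_C,duration"
        assert lines[1] == "27.00,00:00:00"
        assert lines[-1] == "39.00,01:00:00"
        again = read_profile_csv(path)
        assert again == default_recovery_profile()

    @pytest.mark.parametrize(
        "body, match",
        [
            ("target_C,duration\n27.00,bogus\n", "line 2"),
            ("target_C,duration\nabc,00:00:00\n", "line 2"),
            ("wrong,header\n27.00,00:00:00\n", "header"),
            ("target_C,duration\n27.00,00:99:00\n", "line 2"),
        ],
    )
    def test_malformed_profile_files_name_the_line(self, tmp_path, body, match):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(ValueError, match=match):
            read_profile_csv(path)


class TestRequiredBathDrop:
    def test_perfectly_tracking_jar_needs_only_the_target_drop(self, spec):
        d = required_bath_drop_for_jar_drop(HeatTransferModel(50.0, 39.0), spec)
        assert d == pytest.approx(spec.target_jar_drop, abs=0.05)

    def test_reference_rate_constant_regime(self, spec, model):
        d = required_bath_drop_for_jar_drop(model, spec)
        assert 9.0 < d < 13.0
        # consistent with the empirically observed ~12 degC bath drop
        assert abs(d - 12.0) <= 1.5

    def test_monotone_decreasing_in_rate_constant(self, spec, model):
        d_slow = required_bath_drop_for_jar_drop(model, spec)
        d_fast = required_bath_drop_for_jar_drop(HeatTransferModel(1.0, 39.0), spec)
        assert d_fast < d_slow

    def test_bisection_agrees_with_grid_scan(self, spec, model):
        d = required_bath_drop_for_jar_drop(model, spec, tol=0.01)
        grid = np.arange(9.0, 13.0, 0.01)
        for g in grid:
            bath = _instant_drop_bath(spec, g, 0.05, 10.0)
            if _jar_excursion(bath, model.rate_constant, 39.0) >= spec.target_jar_drop:
                break
        assert abs(d - g) <= 0.02

    def test_unreachable_target_names_the_cold_source(self, model):
        spec = DrinkingEventSpec(target_jar_drop=34.5)
        with pytest.raises(InfeasibleDesignError, match="degC water"):
            required_bath_drop_for_jar_drop(model, spec)


class TestPlanEvent:
    def test_default_plan_is_internally_consistent(self, default_plan, spec):
        p = default_plan
        assert sum(p.stage_volumes) == pytest.approx(p.cold_volume)
        assert (
            spec.bath_volume + p.cold_volume - p.removed_volume
            <= spec.bath_capacity + 1e-9
        )
        assert p.expected_jar_drop <= p.expected_bath_drop
        assert p.expected_jar_drop == pytest.approx(spec.target_jar_drop, abs=0.05)
        assert 4.0 < p.cold_volume < 8.0
        assert p.profile.activation_temp == pytest.approx(
            spec.baseline_temp - p.expected_bath_drop, abs=0.005
        )

    def test_tiny_drop_with_huge_capacity_is_single_stage(self, model):
        spec = DrinkingEventSpec(target_jar_drop=0.5, bath_capacity=100.0)
        p = plan_event(spec, model)
        assert not p.staged
        assert p.removed_volume == 0.0
        assert p.stage_volumes == (p.cold_volume,)

    def test_capacity_pressure_forces_staging(self, model):
        spec = DrinkingEventSpec(bath_capacity=16.0)
        p = plan_event(spec, model)
        assert p.staged
        assert p.stage_volumes[0] == pytest.approx(16.0 - 12.5)
        assert p.removed_volume == pytest.approx(p.stage_volumes[1])
        assert 12.5 + p.cold_volume - p.removed_volume <= 16.0 + 1e-9

    @pytest.mark.parametrize("k", [0.2, 0.33, 0.6])
    def test_design_simulate_round_trip(self, spec, k):
        model = HeatTransferModel(k, 39.0)
        plan = plan_event(spec, model)
        _, jar = simulate_event(plan, model)
        achieved = 39.0 - jar.temps.min()
        assert achieved == pytest.approx(spec.target_jar_drop, abs=0.1)
        assert achieved == pytest.approx(plan.expected_jar_drop, abs=0.1)

    def test_plan_validation_catches_inconsistencies(self, spec):
        with pytest.raises(ValueError, match="sum"):
            EventPlan(7.0, True, (4.5, 3.5), 3.5, 12.0, 9.0,
                      default_recovery_profile(), spec)
        with pytest.raises(ValueError, match="attenuation"):
            EventPlan(7.0, True, (4.5, 2.5), 3.5, 9.0, 12.0,
                      default_recovery_profile(), spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DrinkingEventSpec(target_jar_drop=40.0)
        with pytest.raises(ValueError):
            DrinkingEventSpec(bath_volume=25.0)
        with pytest.raises(ValueError):
            DrinkingEventSpec(recovery_threshold_mode="nope")


class TestSimulateEvent:
    def test_episode_returns_to_baseline(self, protocol_event):
        bath, jar = protocol_event
        assert abs(bath.temps[-1] - 39.0) <= 0.10
        assert abs(jar.temps[-1] - 39.0) <= 0.10

    def test_concatenated_episodes_repeat_periodically(self, model, default_plan):
        plan3 = replace(default_plan, spec=replace(default_plan.spec, n_iterations=3))
        bath, jar = simulate_event(plan3, model)
        single_bath, _ = simulate_event(default_plan, model)
        n = len(single_bath)
        assert len(bath) == 3 * n
        chunks = jar.temps.reshape(3, n)
        mins = chunks.min(axis=1)
        argmins = chunks.argmin(axis=1)
        assert np.allclose(mins, mins[0], atol=1e-9)       # three equal minima
        assert np.all(argmins == argmins[0])               # at the same phase
        assert np.ptp(np.diff(argmins + np.arange(3) * n)) == 0  # period = episode

    def test_jar_minimum_lags_bath_minimum_across_rates(self, default_plan):
        for k in (0.2, 0.33, 0.6):
            model = HeatTransferModel(k, 39.0)
            bath, jar = simulate_event(default_plan, model)
            assert jar_minimum(jar)[0] > jar_minimum(bath)[0]

    def test_unreachable_activation_raises(self, default_plan, model):
        # anchor far below what the addition can reach
        bad_profile = RampProfile(20.0, ((20.0, 0.0), (39.0, 120.0)))
        bad = replace(default_plan, profile=bad_profile)
        with pytest.raises(InfeasibleDesignError, match="activate"):
            simulate_event(bad, model)


class TestRecoveryPeriod:
    def test_pure_exponential_pct90_crosses_at_tau_ln_ten(self):
        tau = 26.06
        t = np.arange(0.0, 200.0, 0.05)
        tr = TemperatureTrace(t, 39.0 - 9.0 * np.exp(-t / tau))
        assert recovery_period(tr, 39.0, "pct90") == pytest.approx(tau * np.log(10), abs=0.1)

    def test_threshold_ordering_for_a_deep_drop(self):
        # drop 12 degC: the percentage criteria tolerate residual deficits of
        # 1.2 degC (pct90) and 0.12 degC (pct99), both looser than the 0.10
        # degC absolute band, so the absolute criterion takes longest
        t = np.arange(0.0, 400.0, 0.05)
        tr = TemperatureTrace(t, 39.0 - 12.0 * np.exp(-t / 20.0))
        p_abs = recovery_period(tr, 39.0, "abs_0.10C")
        p90 = recovery_period(tr, 39.0, "pct90")
        p99 = recovery_period(tr, 39.0, "pct99")
        assert p99 >= p90
        assert p_abs >= p99  # 0.10 degC is tighter than 1% of a >10 degC drop

    def test_threshold_ordering_flips_for_a_shallow_drop(self):
        # drop 0.5 degC: 10% of the drop (0.05) is tighter than 0.10 absolute
        t = np.arange(0.0, 400.0, 0.05)
        tr = TemperatureTrace(t, 39.0 - 0.5 * np.exp(-t / 20.0))
        assert recovery_period(tr, 39.0, "pct90") >= recovery_period(tr, 39.0, "abs_0.10C")

    def test_flat_trace_has_no_event(self):
        tr = TemperatureTrace([0.0, 1.0, 2.0], [39.0, 39.0, 39.0])
        with pytest.raises(ValueError, match="below baseline"):
            recovery_period(tr, 39.0)

    def test_unrecovered_trace_reports_the_deficit(self):
        t = np.arange(0.0, 10.0, 0.5)
        tr = TemperatureTrace(t, 39.0 - 9.0 * np.exp(-t / 50.0))
        with pytest.raises(NotRecoveredError) as err:
            recovery_period(tr, 39.0, "pct99")
        assert err.value.deficit > 0

    def test_measured_from_the_minimum_not_the_event_start(self):
        # V shape with a long pre-minimum tail: period counts from the min
        times = np.array([0.0, 50.0, 51.0, 52.0, 53.0])
        temps = np.array([39.0, 30.0, 35.0, 38.5, 38.95])
        assert recovery_period(TemperatureTrace(times, temps), 39.0, "abs_0.10C") == 3.0
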