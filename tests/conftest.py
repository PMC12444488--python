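import numpy as np
import pytest

import drinksim as ds


@pytest.fixture(scope="session")
def model():
    """Reference jar response: k = 0.33 per minute, starting at baseline."""
    return ds.HeatTransferModel(0.33, 39.0)


@pytest.fixture(scope="session")
def spec():
    return ds.DrinkingEventSpec()


@pytest.fixture(scope="session")
def default_plan(spec, model):
    """Episode plan for the default 9-degC jar-drop target."""
    return ds.plan_event(spec, model)


@pytest.fixture(scope="session")
def protocol_event(model):
    """Forward-simulated reference protocol (staged 7 L addition): (bath, jar)."""
    return ds.simulate_event(ds.protocol_plan(), model)


@pytest.fixture(scope="session")
def seven_litre_plan(spec):
    """Single 7 L cold-water addition with the standard ramp."""
    return ds.EventPlan(
        cold_volume=7.0,
        staged=False,
        stage_volumes=(7.0,),
        removed_volume=0.0,
        expected_bath_drop=12.0,
        expected_jar_drop=9.0,
        profile=ds.default_recovery_profile(),
        spec=spec,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_piecewise_bath(rng, n_segments=5, span=30.0):
    """A random piecewise-linear bath trace starting at t=0."""
    knots = np.unique(
        np.concatenate([[0.0], np.sort(rng.uniform(span / 20, span, n_segments))])
    )
    temps = rng.uniform(25.0, 41.0, knots.size)
    return ds.TemperatureTrace(knots, temps, label="bath")
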