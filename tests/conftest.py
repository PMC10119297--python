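import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_minutes(
    concentrations,
    species="CO2",
    plot_id=3,
    setpoint=550.0,
    system_on=True,
    start="2009-07-01 08:00",
    wind_speed=2.0,
    wind_direction=202.5,
):
    """Build a 1-minute record frame from a concentration sequence."""
    conc = np.asarray(concentrations, dtype=float)
    n = conc.size
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="min")
    on = np.broadcast_to(np.asarray(system_on, dtype=bool), (n,))
    return pd.DataFrame(
        {
            "timestamp": ts,
            "plot_id": plot_id,
            "species": species,
            "concentration": conc,
            "setpoint": setpoint,
            "valve_setting": np.where(on, 3.0, 0.0),
            "wind_speed": wind_speed,
            "wind_direction": wind_direction,
            "system_on": on,
        }
    )


@pytest.fixture
def minutes_factory():
    return make_minutes
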