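import pandas as pd
import pytest
from hypothesis import settings

import iptet

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def scenario():
    return iptet.scenario_2019()


@pytest.fixture(scope="session")
def met(scenario):
    return iptet.generate_microclimate(scenario, seed=11)


@pytest.fixture(scope="session")
def crop(scenario):
    return iptet.generate_crop(scenario)


@pytest.fixture(scope="session")
def soil(scenario):
    return iptet.generate_soil_moisture(scenario, seed=12)


@pytest.fixture(scope="session")
def hourly_et(scenario, met, crop, soil):
    return iptet.simulate_et(
        met, crop, soil, senescence_onset=scenario.senescence_onset
    )


@pytest.fixture(scope="session")
def hourly_table(met, hourly_et):
    """Drivers + simulated ET in one hourly table for path analysis."""
    return pd.concat([met.drop(columns="stage"), hourly_et[["ET"]]], axis=1)
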