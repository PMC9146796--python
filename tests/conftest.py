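import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spheropd import (
    ChannelTransport,
    ConcentrationProfile,
    GrowthSimParams,
    SectionSimParams,
    simulate_growth,
    simulate_section,
)


@pytest.fixture(scope="session")
def chip_transport() -> ChannelTransport:
    """The 21 x 2 x 1 mm channel at 2 uL/min with oxaliplatin diffusivity."""
    return ChannelTransport()


@pytest.fixture
def exponential_profile() -> ConcentrationProfile:
    """Noiseless total-drug curve C(t) = 2 exp(-0.1 t) uM sampled over 30 h."""
    t = np.linspace(0.0, 30.0, 16)
    return ConcentrationProfile(times=t, concentrations=2.0 * np.exp(-0.1 * t))


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Hand-written growth records: control 100->300, treated 100->160 mm3."""
    rows = []
    for i, (v0, v7) in enumerate([(100.0, 250.0), (100.0, 350.0)]):
        rows += [(f"c{i}", "control", 0.0, v0), (f"c{i}", "control", 7.0, v7)]
    for i, (v0, v7) in enumerate([(100.0, 140.0), (100.0, 180.0)]):
        rows += [(f"t{i}", "treated", 0.0, v0), (f"t{i}", "treated", 7.0, v7)]
    return pd.DataFrame(rows, columns=["spheroid_id", "condition", "day", "volume_mm3"])


@pytest.fixture(scope="session")
def default_growth_records() -> pd.DataFrame:
    return simulate_growth(GrowthSimParams(seed=7))


@pytest.fixture(scope="session")
def default_section() -> pd.DataFrame:
    return simulate_section(SectionSimParams(seed=11))
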