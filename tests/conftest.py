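import numpy as np
import pandas as pd
import pytest

from guvmech import (
    REFERENCE_SETUP,
    ChannelSetup,
    DEFAULT_CALIBRATION,
    PopulationSpec,
    generate_events,
)


@pytest.fixture(scope="session")
def setup():
    return REFERENCE_SETUP


@pytest.fixture(scope="session")
def dopc_setup():
    """A DOPC-like measurement setup (CellCarrier B at 0.04 uL/s)."""
    return ChannelSetup.from_lab_units(
        channel_um=20.0, flow_ul_s=0.04, medium="CellCarrier B"
    )


@pytest.fixture(scope="session")
def calib():
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def noisy_population(setup):
    """A standard noisy population (K = 0.2 N/m) used by several tests."""
    spec = PopulationSpec(n=2000, K=0.2, seed=42)
    events, truth = generate_events(spec, setup)
    return spec, events, truth


@pytest.fixture
def gated_frame():
    """Small hand-built event table straddling every gate."""
    return pd.DataFrame(
        {
            "area_um": [100.0, 59.0, 230.0, 150.0, 80.0],
            "deform": [0.03, 0.02, 0.05, 0.12, 0.01],
            "porosity": [1.0, 1.0, 1.01, 1.0, 1.05],
        }
    )
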