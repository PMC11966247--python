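import numpy as np
import pytest

import chromsolve as cs


@pytest.fixture(scope="session")
def gor_scenario():
    """Default noise-free glycerol-oxidation scenario."""
    return cs.make_gor_scenario()


@pytest.fixture(scope="session")
def gor_matrix(gor_scenario):
    """Response matrix calibrated from the default scenario."""
    return cs.scenario_response_matrix(gor_scenario)


@pytest.fixture
def gaussian_chromatogram():
    """Amplitude-1 Gaussian peak (sigma = 0.05 min) at 5 min on a fine grid."""
    times = np.linspace(4.0, 6.0, 2001)
    sigma = 0.05
    signals = np.exp(-0.5 * ((times - 5.0) / sigma) ** 2)
    return cs.Chromatogram(cs.RID, times, signals), sigma
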