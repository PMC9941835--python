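import numpy as np
import pytest

from cavclamp import CellModel, PRESETS


@pytest.fixture
def quiet_cell():
    """Noise-free cell with ohmic leak (exercises leak subtraction)."""
    return CellModel(
        capacitance_pF=20.0, leak_conductance_nS=1.5, noise_sd_pA=0.0, seed=7
    )


@pytest.fixture
def clean_cell():
    """Noise-free, leak-free cell (pure channel current)."""
    return CellModel(
        capacitance_pF=20.0, leak_conductance_nS=0.0, noise_sd_pA=0.0, seed=7
    )


@pytest.fixture(params=sorted(PRESETS))
def preset(request):
    return PRESETS[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(20220747)
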