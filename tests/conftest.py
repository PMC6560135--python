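import numpy as np
import pytest

from acetoflux.synthetic_data import SimulationConfig, mini_central_carbon


@pytest.fixture(scope="session")
def fixture_model():
    """The embedded mini-central-carbon model and its reference flux."""
    return mini_central_carbon()


@pytest.fixture()
def noiseless_config():
    return SimulationConfig(
        mu_true=0.6,
        B0_true=0.05,
        yield_true=0.09,
        G0=16.65,
        od_noise_sd=0.0,
        conc_noise_sd=0.0,
        replicate_cv=0.0,
        n_replicates=2,
        seed=123,
        t_grid=np.arange(0.0, 4.01, 0.5),
    )
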