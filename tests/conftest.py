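import numpy as np
import pytest

from oligocount import pipeline, synthetic


@pytest.fixture(scope="session")
def roundtrip_acq():
    """20 Hz, 500-frame acquisition with unit steps 5 noise SDs deep."""
    return pipeline.make_acquisition()


@pytest.fixture(scope="session")
def noiseless_acq():
    return synthetic.AcquisitionParams(
        noise_model=synthetic.NoiseModel(read_sd=0.0, shot=False)
    )


@pytest.fixture(scope="session")
def small_pie():
    return synthetic.PIEConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
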