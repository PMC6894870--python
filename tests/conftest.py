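import numpy as np
import pytest

import aednns as A


@pytest.fixture(scope="session")
def small_cohort():
    """400+400-row default-parameter cohort for pipeline tests."""
    spec = A.default_spec(n_low=400, n_high=400)
    return A.generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def tiny_specs():
    """Short training profiles so pipeline tests stay fast."""
    return A.AutoencoderSpec(epochs=40), A.DNNSpec(epochs=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
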