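import numpy as np
import pytest

from stnprofiler import STNMixture, STNParams, sample_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_component_mixture():
    """Well-separated bimodal mixture with opposite skews."""
    return STNMixture([0.4, 0.6], (STNParams(0.0, 1.0, 4.0, 5.0),
                                   STNParams(6.0, 1.5, -3.0, 5.0)))


@pytest.fixture
def bimodal_sample(two_component_mixture):
    return sample_mixture(two_component_mixture, 1500, 7)
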