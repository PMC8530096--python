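import numpy as np
import pytest

from mmdisten import EntropyParams, MultichannelSeries, gen_epileptic_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return EntropyParams()


@pytest.fixture
def random_series(rng):
    return MultichannelSeries(values=rng.standard_normal((2, 300)), sampling_rate=100.0)


@pytest.fixture(scope="session")
def small_recording():
    """A short three-state recording shared by pipeline-level tests."""
    return gen_epileptic_like(
        channels=2, segment_minutes=(1.0, 1.0, 0.5), sampling_rate=128.0, seed=11
    )
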