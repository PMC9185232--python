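import numpy as np
import pytest

from nucleiguide import ModelConfig, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest full-variant network that exercises every mechanism."""
    return ModelConfig(
        input_size=8,
        channels_per_stage=(2, 3),
        convs_per_stage=1,
        fusion_depth=2,
        head_hidden=4,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A 30-sample balanced synthetic dataset (default morphology)."""
    from nucleiguide import NucleiGuidedGradingModel

    return NucleiGuidedGradingModel.from_synthetic(SynthConfig(seed=0, n_per_grade=10))
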