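import logging

import numpy as np
import pytest

from casgen.benchmark import benchmark_dataset, train_benchmark
from casgen.model_core import CasGenModel, ModelConfig

# the clamp warnings fired by confidently-wrong early-training predictions
# are expected; keep test output readable
logging.getLogger("casgen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bench_data():
    """The standard 200-sequence two-family benchmark dataset."""
    return benchmark_dataset(seed=0)


@pytest.fixture(scope="session")
def trained_benchmark():
    """Benchmark model trained with the margin loss on (gamma = 1)."""
    return train_benchmark(seed=0, gamma=1.0)


@pytest.fixture(scope="session")
def trained_benchmark_no_margin():
    """Same data and seed, margin loss off (gamma = 0)."""
    return train_benchmark(seed=0, gamma=0.0)


@pytest.fixture
def tiny_config():
    return ModelConfig(
        max_len=16,
        latent_dim=8,
        encoder_layers=2,
        attention_heads=2,
        model_width=16,
        feedforward_width=32,
        decoder_conv_layers=2,
        rng_seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return CasGenModel(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
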