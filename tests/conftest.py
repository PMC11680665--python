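import numpy as np
import pytest

from peatflux import GeneratorConfig, generate_samples


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1, noise_ppm=0.0, noise_delta=0.0)


@pytest.fixture
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture
def sample_pairs(noiseless_config):
    """(Sample, TrueState) pairs drawn under the zero-noise configuration."""
    return generate_samples(noiseless_config)


@pytest.fixture
def media_pair(sample_pairs):
    """First growing-media sample and its ground truth."""
    return next(p for p in sample_pairs if p[0].material == "growing_media")


@pytest.fixture
def peat_pair(sample_pairs):
    return next(p for p in sample_pairs if p[0].material == "peat")


@pytest.fixture
def rng():
    return np.random.default_rng(20240509)
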