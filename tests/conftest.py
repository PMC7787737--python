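import numpy as np
import pytest

from cranioface import synthetic as syn


@pytest.fixture(scope="session")
def small_population():
    """A fast low-resolution corresponded population for pipeline tests."""
    cfg = syn.GeneratorConfig(n_theta=24, n_phi=24, n_samples=22, seed=5)
    samples, truth = syn.sample_population(cfg)
    return cfg, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
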