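import numpy as np
import pytest

from ntcpselect import GeneratorConfig, generate_cohort, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """A 12-patient default-condition cohort shared across tests."""
    config = GeneratorConfig(n_patients=12, seed=7)
    covs, pairs = generate_cohort(config)
    return config, covs, pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def zero_delta_map(registry):
    return {m: 0.0 for m in registry.model_ids}
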