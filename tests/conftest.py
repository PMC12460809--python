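import numpy as np
import pytest

from ringscape import DomainDefinition, EnsembleSpec, generate_ensemble, make_scaffold_model


@pytest.fixture(scope="session")
def domains():
    return DomainDefinition()


@pytest.fixture(scope="session")
def scaffold(domains):
    return make_scaffold_model(domains)


@pytest.fixture(scope="session")
def default_ensemble():
    """The standard study conditions: 5 planted clusters x 6 protomers,
    >= 6 deg hinge steps, 0.3 A coordinate noise."""
    return generate_ensemble(EnsembleSpec(seed=0))


@pytest.fixture(scope="session")
def clean_ensemble():
    """Noise-free single-model-per-cluster ensemble for exact checks."""
    return generate_ensemble(
        EnsembleSpec(seed=0, coordinate_noise_sigma=0.0, protomers_per_cluster=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
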