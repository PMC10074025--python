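import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """Small noiseless-ish panel reused by federation/experiment tests."""
    from feddrf.synth import generate_study

    return generate_study(n_cells=40, n_drugs=8, p_cell=16, p_drug=9,
                          noise_sd=0.2, cluster_effect=0.5, seed=7)
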