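import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome_sim():
    """A 20-gene synthetic genome shared across design-level tests."""
    from crispri_screenkit.simulate import SimGenomeSpec, simulate_genome

    return simulate_genome(SimGenomeSpec(n_genes=20, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
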