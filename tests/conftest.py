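import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def small_genus():
    """A small simulated genus shared by pipeline-level tests."""
    from estssr.simulate import angiosperm_preset, generate_genus_dataset

    spec = angiosperm_preset(seed=42, n_sequences=40)
    return generate_genus_dataset(spec)
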