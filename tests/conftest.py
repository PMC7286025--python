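import pytest
from hypothesis import HealthCheck, settings

from cyanogst.motifs import load_class_definitions
from cyanogst.synthetic import SyntheticConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def classes():
    return load_class_definitions()


@pytest.fixture(scope="session")
def zero_noise(classes):
    """One clean representative per class, with its truth table."""
    return generate(SyntheticConfig(n_per_class=1, mutation_rate=0.0, seed=1), classes)


@pytest.fixture(scope="session")
def low_noise(classes):
    """Two representatives per class at 5% substitution with protected motifs."""
    return generate(
        SyntheticConfig(n_per_class=2, mutation_rate=0.05, seed=5), classes
    )
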