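import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from her2ia.classify import Her2Classifier
from her2ia.stains import ColourDefinition
from her2ia.synthslide import generate_feature_table

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cdef() -> ColourDefinition:
    return ColourDefinition()


@pytest.fixture(scope="session")
def training_table():
    """150 synthetic slides (50 per category preset), analysed end to end."""
    return generate_feature_table(50, seed=1000)


@pytest.fixture(scope="session")
def test_table():
    """90 held-out synthetic slides (30 per category preset)."""
    return generate_feature_table(30, seed=900_000)


@pytest.fixture(scope="session")
def fitted_model(training_table) -> Her2Classifier:
    return Her2Classifier.fit(training_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
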