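import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from utrscreen import MiRNA, StudyConfig, fold_baseline, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def mir129():
    """miR-129-5p, the screen's AU-richest seed (GC 16.7%)."""
    return MiRNA("miR-129-5p", "CUUUUUGCGGUCUGGGCUUGC")


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


@pytest.fixture(scope="session")
def hairpin():
    """Perfect 4-pair GC hairpin with a 4-nt loop."""
    return fold_baseline("GGGGAAAACCCC")


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared across tests."""
    config = StudyConfig(n_genes=8, utr_length_range=(200, 900), rng_seed=11)
    return generate_study(config)
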