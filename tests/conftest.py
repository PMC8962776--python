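import numpy as np
import pytest
from hypothesis import settings

from fundusprog.cohort import series_from_frame
from fundusprog.phantom import SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject manifest-only cohort shared across tests."""
    cfg = SimConfig(n_subjects=30, image_size=64, master_seed=11)
    manifest, phantoms = simulate_cohort(cfg)
    return cfg, manifest, phantoms


@pytest.fixture(scope="session")
def small_series(small_cohort):
    _, manifest, _ = small_cohort
    return series_from_frame(manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
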