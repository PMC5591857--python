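import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "songmem",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("songmem")

from songmem import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small two-group cohort with zero trial noise and a known left-NCM effect."""
    cfg = CohortConfig(
        n_birds_per_group={"hdac3i": 2, "vehicle": 2},
        fi_true={("hdac3i", "left", "NCM"): 2.0},
        electrodes_per_hemisphere_ncm=2,
        electrodes_per_hemisphere_nonncm=2,
        noise_cv=0.0,
        seed=7,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Single-group cohort with the default trial noise, for statistical plumbing."""
    cfg = CohortConfig(
        n_birds_per_group={"hdac3i": 3},
        electrodes_per_hemisphere_ncm=3,
        electrodes_per_hemisphere_nonncm=0,
        seed=11,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
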