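import numpy as np
import pytest

from fcedge import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 30-subject cohort (3 networks, 2x150 volumes) for plumbing tests."""
    spec = CohortSpec(
        group_sizes=(12, 10, 8),
        n_networks=3,
        n_volumes=150,
        effect_edges=(),
        seed=42,
    )
    runs, pheno, truth = simulate_cohort(spec)
    return spec, runs, pheno, truth


@pytest.fixture(scope="session")
def study_scale_cohort():
    """Study-sized cohort (108 subjects, 17 networks) with reduced run length."""
    spec = CohortSpec(n_volumes=200, seed=7)
    runs, pheno, truth = simulate_cohort(spec)
    return spec, runs, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
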