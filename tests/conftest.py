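import numpy as np
import pytest

from dfcstates import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy switching cohort shared across tests (fixed seed)."""
    design = CohortDesign(
        n_subjects=12,
        n_runs=2,
        n_regions=16,
        n_timepoints=150,
        k_true=3,
        seed=101,
    )
    return design, simulate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
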