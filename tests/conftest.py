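import pytest

from ea_trial_sim.outcome_dml import fit_outcome_model
from ea_trial_sim.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort48():
    """Default-condition synthetic cohort (48 patients, fixed seed)."""
    return generate_cohort(CohortConfig(seed=20240612))


@pytest.fixture(scope="session")
def outcome_model48(cohort48):
    return fit_outcome_model(cohort48.records, cohort48.exposures, rng_seed=7)


@pytest.fixture(scope="session")
def cohort_large():
    """Large cohort for distributional-margin checks."""
    return generate_cohort(CohortConfig(n_patients=10000, seed=99))
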