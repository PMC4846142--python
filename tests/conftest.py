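import warnings

import pytest

import steatnet as sn

# Convergence warnings from deliberately tiny training budgets are noise in
# the test log; validation warnings stay visible.
warnings.filterwarnings("ignore", message="network did not converge")


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort with the study's missing-data topology."""
    cohort = sn.generate_cohort(sn.default_config(), seed=7)
    return sn.inject_study_artifacts(cohort, seed=7)


@pytest.fixture(scope="session")
def study_ensemble(study_cohort):
    """Full-variable ensemble on the default synthetic cohort."""
    return sn.run_ensemble(study_cohort, base_seed=1)
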