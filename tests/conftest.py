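import warnings

import pytest

from bistate import (
    CohortConfig,
    PipelineConfig,
    run_experiment_pipeline,
    simulate_cohort,
    strong_coupling_config,
)


@pytest.fixture(scope="session")
def strong_cohort():
    """One 20-patient cohort with strong state-symptom coupling."""
    return simulate_cohort(strong_coupling_config(seed=7))


@pytest.fixture(scope="session")
def strong_report(strong_cohort):
    """Full pipeline report for the strong-coupling cohort."""
    trials, profiles, _ = strong_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment_pipeline(
            trials, profiles, PipelineConfig(seed=11, kmeans_iterations=25)
        )


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=3))
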