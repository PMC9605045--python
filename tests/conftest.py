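import pytest
from hypothesis import HealthCheck, settings

from alushare import PipelineConfig, SimulationConfig, run_cohort, simulate_cohort

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with no divergence and no corruption events."""
    cfg = SimulationConfig(
        seed=101, n_loci=40, per_lineage_divergence=0.0,
        np_event_rate=0.0, n_run_rate=0.0, truncation_rate=0.0, fragment_rate=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_cohort):
    return run_cohort(clean_cohort, PipelineConfig())


@pytest.fixture(scope="session")
def corrupt_cohort():
    """Cohort with 2% per-lineage divergence and all corruption events on."""
    cfg = SimulationConfig(
        seed=213, n_loci=60, per_lineage_divergence=0.02,
        np_event_rate=0.1, n_run_rate=0.05, truncation_rate=0.05, fragment_rate=0.05,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def corrupt_result(corrupt_cohort):
    return run_cohort(corrupt_cohort, PipelineConfig())
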