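import pytest

from authsieve.auto_battery import run_battery
from authsieve.cohort_model import ThresholdConfig
from authsieve.manual_review import run_manual_stage
from authsieve.synth_cohort import generate_cohort

DEFAULT_SEED = 20210831


@pytest.fixture(scope="session")
def config() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The default archetype-mix cohort (1224 dossiers) at the study seed."""
    return generate_cohort(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """One full pipeline run over the default cohort: (cohort, decisions, cases)."""
    cohort = default_cohort
    decisions = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    cases = run_manual_stage(
        decisions,
        {d.participant_id: d for d in cohort.dossiers},
        cohort.manual_evidence,
        cohort.registry,
        cohort.lookups,
        cohort.config,
        cohort.conflict_rules,
    )
    return cohort, decisions, cases
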