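import warnings

import pytest

from thoracic_cea import costing, pipeline, synthetic_trial, utility


@pytest.fixture(scope="session")
def value_set() -> utility.ValueSet:
    return utility.load_value_set()


@pytest.fixture(scope="session")
def catalog() -> costing.DRGCatalog:
    return costing.DRGCatalog.load_default()


@pytest.fixture(scope="session")
def rules() -> costing.RehospRules:
    return costing.RehospRules.load_default()


@pytest.fixture(scope="session")
def small_trial():
    """A modest simulated cohort shared by the comparative/uncertainty tests."""
    cfg = synthetic_trial.TrialConfig(seed=42, n_per_arm=60)
    patients = synthetic_trial.generate_trial(cfg)
    observations = synthetic_trial.simulate_eq5d(patients, cfg)
    observations = synthetic_trial.apply_missingness(observations, cfg, patients)
    stays = synthetic_trial.simulate_resource_use(patients, cfg)
    return cfg, patients, observations, stays


@pytest.fixture(scope="session")
def analysis_table(small_trial):
    """Per-patient cost/QALY table built from the shared cohort (uncostable
    stays excluded with their warnings silenced)."""
    cfg, patients, observations, stays = small_trial
    patients_df = synthetic_trial.patients_frame(patients)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        stays = pipeline.stage_cost(list(stays), patients_df)
        return pipeline.build_analysis_table(patients_df, observations, stays)
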