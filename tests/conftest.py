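import warnings

import pandas as pd
import pytest

import periomed as pm

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


def merge_final_visit(cohort: pm.SyntheticCohort) -> pd.DataFrame:
    """Final-visit clinical records with the true response category merged in."""
    final_month = max(cohort.clinical["visit_month"])
    final = cohort.clinical[cohort.clinical["visit_month"] == final_month]
    final = final.set_index("subject_id").copy()
    final["category"] = cohort.truth.subjects["category"]
    return final.reset_index()


def baseline_subjects(cohort: pm.SyntheticCohort) -> pd.DataFrame:
    """Per-subject truth joined with baseline covariates."""
    base = cohort.clinical[cohort.clinical["visit_month"] == 0]
    return cohort.truth.subjects.join(
        base.set_index("subject_id")[["age_band", "sex", "smoking", "arm"]]
    )


@pytest.fixture(scope="session")
def small_cohort() -> pm.SyntheticCohort:
    """Reduced cohort (20 patients, ~2000 reads) for topic-model tests."""
    cfg = pm.CohortConfig(seed=7, n_patients=20, library_size_mean=2000.0)
    return pm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> pm.SyntheticCohort:
    """One full-size cohort at generator defaults."""
    return pm.generate_cohort(pm.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_final_records(default_cohort) -> pd.DataFrame:
    return merge_final_visit(default_cohort)


@pytest.fixture(scope="session")
def default_baseline_subjects(default_cohort) -> pd.DataFrame:
    return baseline_subjects(default_cohort)
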