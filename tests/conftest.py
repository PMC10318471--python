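import numpy as np
import pandas as pd
import pytest

from panelmsm import schema
from panelmsm.pipeline import AnalysisConfig
from panelmsm.growth import GrowthModelSpec
from panelmsm.prep import prepare_panel
from panelmsm.simulate import SimParams, simulate_cohort


def make_panel(records: list[dict]) -> pd.DataFrame:
    """Build a small panel from row dicts, filling schema defaults."""
    defaults = {
        schema.TIME: None,
        schema.STATUS: schema.ACTIVE,
        schema.RESPONDED: 1,
        schema.EXPOSURE: 0.0,
        schema.OUTCOME: 0.0,
        "age0": 70.0,
        "sex": 1.0,
        "education_years": 12.0,
        "race_group": 1.0,
        "parental_edu_gt_hs": 0.0,
        "born_south": 0.0,
        "married": 1.0,
        "log_eq_income": 10.0,
        "log_eq_wealth": 11.0,
        "chronic_count": 1.0,
        "depressive_sx": 1.0,
        "bmi": 27.0,
        "drinks": 0.0,
        "smokes": 0.0,
    }
    rows = []
    for rec in records:
        row = {**defaults, **rec}
        if row[schema.TIME] is None:
            row[schema.TIME] = row[schema.WAVE] * schema.YEARS_PER_WAVE
        if row[schema.STATUS] != schema.ACTIVE:
            for col in [schema.EXPOSURE, schema.OUTCOME] + schema.TIMEVARYING_COVARIATES:
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


GLS_CONFIG = AnalysisConfig(growth_spec=GrowthModelSpec(estimator="weighted_gls_independence"))


@pytest.fixture(scope="session")
def default_cohort():
    """One medium default-parameter cohort shared across tests."""
    params = SimParams(n_subjects=10_000, seed=42)
    panel, truth = simulate_cohort(params)
    return params, panel, truth


@pytest.fixture(scope="session")
def default_prepped(default_cohort):
    _, panel, _ = default_cohort
    prepped, _ = prepare_panel(panel)
    return prepped


@pytest.fixture(scope="session")
def default_analysis(default_prepped):
    from panelmsm.pipeline import analyze_panel

    return analyze_panel(default_prepped, GLS_CONFIG, with_balance=True)


@pytest.fixture(scope="session")
def default_weights(default_analysis):
    return default_analysis.weights
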