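"""Column schema and validation for the long-format person-wave panel.

The panel is a tidy :class:`pandas.DataFrame` with one row per person-wave.
Rows exist for every wave from 0 up to (and including) the first wave at
which a person is lost to follow-up or dies; the terminal row carries the
status flag but no measurements.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

#: years between consecutive waves (biennial design)
YEARS_PER_WAVE = 2.0

# status flags -------------------------------------------------------------
ACTIVE = "active"
LOST = "lost"
DEAD = "dead"
STATUSES = (ACTIVE, LOST, DEAD)

# core identifier / bookkeeping columns ------------------------------------
ID = "person_id"
WAVE = "wave"
TIME = "time_years"
STATUS = "status"
RESPONDED = "responded"

EXPOSURE = "exposure"
OUTCOME = "outcome"
CENSOR = "censor"  # added by build_censoring_indicators

#: time-invariant baseline covariates (V)
BASELINE_COVARIATES = [
    "age0",
    "sex",
    "education_years",
    "race_group",
    "parental_edu_gt_hs",
    "born_south",
]

#: time-varying covariates (L)
TIMEVARYING_COVARIATES = [
    "married",
    "log_eq_income",
    "log_eq_wealth",
    "chronic_count",
    "depressive_sx",
    "bmi",
    "drinks",
    "smokes",
]

#: default L subset used in the weight models (kept low-dimensional so the
#: per-wave propensity fits stay well conditioned at modest sample sizes)
MODEL_TIMEVARYING = ["married", "log_eq_income", "chronic_count", "depressive_sx"]

#: optional alternative early-life SES proxy (sensitivity analysis)
CHILDHOOD_SES = "childhood_ses"

#: health covariates that the ``health_time_invariant`` scenario freezes
HEALTH_COVARIATES = ["chronic_count", "depressive_sx"]

REQUIRED_COLUMNS = (
    [ID, WAVE, TIME, STATUS, RESPONDED, EXPOSURE, OUTCOME]
    + BASELINE_COVARIATES
    + TIMEVARYING_COVARIATES
)

COLUMN_DICTIONARY = {
    ID: "person identifier",
    WAVE: "0-based wave index (biennial)",
    TIME: "years since baseline (= 2 * wave)",
    STATUS: "per-wave status: active / lost / dead (absorbing)",
    RESPONDED: "1 if the person responded at this wave",
    EXPOSURE: "binary exposure (1 = exposed), empty if missing",
    OUTCOME: "continuous outcome in SD units, empty if missing",
    "age0": "baseline age in years (time-invariant)",
    "sex": "1 = female (time-invariant)",
    "education_years": "years of education (time-invariant)",
    "race_group": "1 = reference racial/ethnic group (time-invariant)",
    "parental_edu_gt_hs": "1 = parental education beyond high school",
    "born_south": "1 = born in a southern state",
    "married": "1 = married or partnered",
    "log_eq_income": "log of household-size-equivalized income",
    "log_eq_wealth": "signed log of equivalized wealth",
    "chronic_count": "number of chronic conditions (0-8)",
    "depressive_sx": "depressive symptom count (0-8)",
    "bmi": "body mass index",
    "drinks": "1 = current drinker",
    "smokes": "1 = current smoker",
    CHILDHOOD_SES: "continuous early-life SES proxy (optional column)",
    CENSOR: "1 at first wave lost to follow-up, 0 while observed, "
    "empty at/after death and after loss",
}


class PanelError(ValueError):
    """Raised when a panel violates the schema contract."""


def validate_panel(panel: pd.DataFrame, require_censor: bool = False) -> None:
    """Check schema and the per-person status contract.

    Raises :class:`PanelError` on missing columns, unknown status flags,
    non-contiguous wave indices, or a non-monotone status sequence
    (anything following ``lost`` or ``dead``).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelError(f"panel is missing required columns: {missing}")
    if require_censor and CENSOR not in panel.columns:
        raise PanelError("panel lacks censoring indicators; run build_censoring_indicators")
    bad = set(panel[STATUS].unique()) - set(STATUSES)
    if bad:
        raise PanelError(f"unknown status values: {sorted(bad)}")

    df = panel.sort_values([ID, WAVE])
    waves = df.groupby(ID, sort=False)[WAVE]
    first = waves.first()
    if (first != 0).any():
        raise PanelError("every person must have a wave-0 row")
    gaps = waves.diff().dropna()
    if (gaps != 1).any():
        raise PanelError("wave indices must be contiguous per person")

    # terminal statuses are absorbing: nothing may follow lost/dead
    terminal = df[STATUS].isin([LOST, DEAD]).to_numpy()
    same_person = (df[ID].to_numpy()[1:] == df[ID].to_numpy()[:-1])
    if np.any(terminal[:-1] & same_person):
        raise PanelError("status is not monotone: rows exist after lost/dead")

    # no measurements on terminal rows
    term_rows = df.loc[df[STATUS] != ACTIVE]
    value_cols = [EXPOSURE, OUTCOME] + TIMEVARYING_COVARIATES
    if len(term_rows) and term_rows[value_cols].notna().to_numpy().any():
        raise PanelError("lost/dead rows must not carry exposure, outcome or covariates")


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a panel as tidy CSV with a JSON column-dictionary sidecar."""
    path = Path(path)
    panel.to_csv(path, index=False, na_rep="")
    sidecar = {c: COLUMN_DICTIONARY.get(c, "") for c in panel.columns}
    path.with_suffix(".columns.json").write_text(json.dumps(sidecar, indent=2))


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a tidy-CSV panel, restoring dtypes (empty fields become NaN)."""
    panel = pd.read_csv(path, dtype={ID: np.int64, WAVE: np.int64, STATUS: str})
    return panel
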