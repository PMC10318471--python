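"""Turn a raw person-wave panel into the analysis-ready panel.

Covers exposure coding from the two survey items, eligibility filtering,
income/wealth equivalization transforms, last-observation-carried-forward
imputation, and construction of censoring indicators that treat death as a
competing terminal event rather than censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import schema
from .schema import ACTIVE, CENSOR, EXPOSURE, ID, LOST, OUTCOME, STATUS, WAVE

__all__ = [
    "PrepConfig",
    "LogPolicy",
    "code_food_insecurity",
    "code_food_insecurity_frame",
    "apply_eligibility",
    "locf_impute",
    "equivalize_and_log",
    "build_censoring_indicators",
    "prepare_panel",
]

YES, NO, DONT_KNOW, REFUSED, MISSING = "yes", "no", "dont_know", "refused", "missing"
_Q1_VALUES = {YES, NO, DONT_KNOW, REFUSED, MISSING}
_Q2_VALUES = {YES, NO, MISSING}


class LogPolicy(str, Enum):
    """Log transform applied to equivalized amounts."""

    PLAIN_LOG = "plain_log"  # ln(x); requires x > 0
    SIGNED_LOG1P = "signed_log1p"  # sign(x) * log1p(|x|); total and monotone


@dataclass(frozen=True)
class PrepConfig:
    baseline_wave: int = 0
    min_baseline_age: float = 50.0
    locf_enabled: bool = True
    log_policy: LogPolicy = LogPolicy.SIGNED_LOG1P
    complete_case: bool = False

    def __post_init__(self) -> None:
        if self.min_baseline_age < 0:
            raise ValueError(f"min_baseline_age must be >= 0, got {self.min_baseline_age}")


def code_food_insecurity(q1: str, q2: str = MISSING) -> float:
    """Code one exposure response from the two survey items.

    ``q1`` answers "always had enough money for food"; ``q2`` (asked only of
    those not answering yes to q1) answers "ever ate less than they should".
    Returns 1.0 (insecure), 0.0 (secure) or ``nan`` (no information).
    """
    if q1 not in _Q1_VALUES:
        raise ValueError(f"invalid q1 response: {q1!r}")
    if q2 not in _Q2_VALUES:
        raise ValueError(f"invalid q2 response: {q2!r}")
    if q1 == YES:
        if q2 != MISSING:
            raise ValueError("q2 may not be populated when q1 is 'yes'")
        return 0.0
    if q1 == NO:
        return 1.0
    if q1 in (DONT_KNOW, REFUSED):
        if q2 == YES:
            return 1.0
        if q2 == NO:
            return 0.0
        return float("nan")
    # q1 missing entirely
    if q2 == YES:
        return 1.0
    if q2 == NO:
        return 0.0
    return float("nan")


def code_food_insecurity_frame(responses: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`code_food_insecurity` over columns ``q1``/``q2``."""
    return responses.apply(lambda r: code_food_insecurity(r["q1"], r["q2"]), axis=1)


def apply_eligibility(
    panel: pd.DataFrame, cfg: PrepConfig = PrepConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility filters in fixed order and count exclusions.

    Order: baseline age >= ``min_baseline_age``, then non-missing baseline
    exposure, then at least one non-missing outcome at any wave.  Raises
    ``ValueError`` if no person survives the filters.
    """
    w0 = panel.loc[panel[WAVE] == cfg.baseline_wave].set_index(ID)
    all_ids = w0.index

    under_age = w0.index[w0["age0"] < cfg.min_baseline_age]
    rest = all_ids.difference(under_age)
    no_exposure = w0.loc[rest].index[w0.loc[rest, EXPOSURE].isna()]
    rest = rest.difference(no_exposure)
    any_outcome = panel.groupby(ID)[OUTCOME].apply(lambda s: s.notna().any())
    no_outcome = rest[~any_outcome.reindex(rest).fillna(False)]
    rest = rest.difference(no_outcome)

    log = {
        "age": int(len(under_age)),
        "exposure": int(len(no_exposure)),
        "outcome": int(len(no_outcome)),
    }
    if len(rest) == 0:
        raise ValueError(f"no persons remain after eligibility filters ({log})")
    out = panel.loc[panel[ID].isin(rest)].reset_index(drop=True)
    return out, log


_LOCF_COLUMNS = [EXPOSURE] + schema.TIMEVARYING_COVARIATES


def locf_impute(panel: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Carry the last observed exposure/covariate value forward.

    Filling happens only at waves where the person is alive and under
    observation (status ``active``); outcomes are never imputed, nothing is
    carried into lost/dead waves, and values missing before any observation
    stay missing.  Idempotent.
    """
    df = panel.sort_values([ID, WAVE]).reset_index(drop=True)
    cols = [c for c in (columns if columns is not None else _LOCF_COLUMNS) if c in df.columns]
    filled = df.groupby(ID, sort=False)[cols].ffill()
    active = (df[STATUS] == ACTIVE).to_numpy()
    for c in cols:
        df[c] = np.where(active, filled[c].to_numpy(), df[c].to_numpy())
    return df


def equivalize_and_log(
    amount: float | np.ndarray,
    household_size: int | np.ndarray,
    policy: LogPolicy = LogPolicy.SIGNED_LOG1P,
) -> float | np.ndarray:
    """Equivalize by sqrt household size, then apply the configured log.

    ``signed_log1p`` maps x to sign(x) * log1p(|x|), a total monotone
    transform that tolerates the zero and negative values that occur in
    wealth data; ``plain_log`` is the natural log and requires positivity.
    """
    amount = np.asarray(amount, dtype=float)
    hh = np.asarray(household_size, dtype=float)
    if np.any(hh < 1):
        raise ValueError("household_size must be >= 1")
    eq = amount / np.sqrt(hh)
    if policy == LogPolicy.PLAIN_LOG:
        if np.any(eq <= 0):
            raise ValueError("plain_log policy requires strictly positive amounts")
        out = np.log(eq)
    else:
        out = np.sign(eq) * np.log1p(np.abs(eq))
    return float(out) if out.ndim == 0 else out


def build_censoring_indicators(panel: pd.DataFrame) -> pd.DataFrame:
    """Add the per-wave censoring indicator ``C``.

    C = 0 while active, 1 at the first wave a living person is lost to
    follow-up, and undefined (NaN) at and after death — the dead contribute
    no censoring risk sets.  Input status must be monotone.
    """
    df = panel.sort_values([ID, WAVE]).reset_index(drop=True)
    status = df[STATUS].to_numpy()
    same = df[ID].to_numpy()[1:] == df[ID].to_numpy()[:-1]
    if np.any((status[:-1] != ACTIVE) & same):
        raise ValueError("non-monotone status: rows follow a lost/dead wave")
    c = np.where(status == ACTIVE, 0.0, np.where(status == LOST, 1.0, np.nan))
    df[CENSOR] = c
    return df


def prepare_panel(
    panel: pd.DataFrame, cfg: PrepConfig = PrepConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full prep: eligibility -> LOCF (unless disabled) -> censoring flags."""
    out, log = apply_eligibility(panel, cfg)
    if cfg.locf_enabled and not cfg.complete_case:
        out = locf_impute(out)
    out = build_censoring_indicators(out)
    return out, log
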