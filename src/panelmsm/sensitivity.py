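"""Sensitivity scenarios: re-run the full pipeline under documented
single-change variations of the base analysis and collate the results.

Scenarios:

* ``recode_missing_secure`` / ``recode_missing_insecure`` — instead of
  carrying exposure forward, recode missing post-baseline exposure as
  unexposed / exposed (covariates are still carried forward).
* ``complete_case`` — no carry-forward at all; person-waves with missing
  exposure or model covariates drop out of risk sets and the fit.
* ``health_time_invariant`` — the treatment-weight denominator uses
  baseline values of the health covariates at every wave; censoring-weight
  models keep them time-varying.
* ``alt_childhood_ses`` — replaces the parental-education baseline
  covariate with the continuous early-life SES proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema
from .growth import MSMResult
from .pipeline import AnalysisConfig, analyze_panel
from .prep import PrepConfig, apply_eligibility, build_censoring_indicators, locf_impute

__all__ = ["Scenario", "SCENARIO_NAMES", "run_scenario", "collate_scenarios"]

SCENARIO_NAMES = (
    "base",
    "recode_missing_secure",
    "recode_missing_insecure",
    "complete_case",
    "health_time_invariant",
    "alt_childhood_ses",
)


@dataclass(frozen=True)
class Scenario:
    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")


def _prep_for_scenario(
    panel: pd.DataFrame, scenario: Scenario, prep_cfg: PrepConfig
) -> pd.DataFrame:
    out, _ = apply_eligibility(panel, prep_cfg)
    covariate_cols = list(schema.TIMEVARYING_COVARIATES)
    if scenario.name in ("recode_missing_secure", "recode_missing_insecure"):
        out = locf_impute(out, columns=covariate_cols)
        fill = 0.0 if scenario.name == "recode_missing_secure" else 1.0
        active = out[schema.STATUS] == schema.ACTIVE
        missing = out[schema.EXPOSURE].isna() & active
        out.loc[missing, schema.EXPOSURE] = fill
    elif scenario.name == "complete_case":
        pass  # no imputation at all
    else:
        out = locf_impute(out)
    return build_censoring_indicators(out)


def _config_for_scenario(scenario: Scenario, base: AnalysisConfig) -> AnalysisConfig:
    if scenario.name == "health_time_invariant":
        return replace(base, freeze_health_in_treatment=True)
    if scenario.name == "alt_childhood_ses":
        v_cols = tuple(
            schema.CHILDHOOD_SES if c == "parental_edu_gt_hs" else c
            for c in base.weight_spec.baseline_covariates
        )
        return replace(base, weight_spec=replace(base.weight_spec, baseline_covariates=v_cols))
    return base


def run_scenario(
    panel: pd.DataFrame,
    scenario: Scenario,
    base_config: AnalysisConfig = AnalysisConfig(),
    prep_cfg: PrepConfig = PrepConfig(),
) -> MSMResult:
    """Apply one scenario to a *raw* panel and return the refitted result.

    Exactly one base behaviour changes per scenario; conflicts between the
    scenario and the base configuration are rejected up front.
    """
    if scenario.name == "alt_childhood_ses" and schema.CHILDHOOD_SES not in panel.columns:
        raise ValueError("alt_childhood_ses requires the childhood_ses column")
    if scenario.name == "health_time_invariant" and base_config.freeze_health_in_treatment:
        raise ValueError("base config already freezes health covariates; scenario is redundant")
    config = _config_for_scenario(scenario, base_config)
    prepped = _prep_for_scenario(panel, scenario, prep_cfg)
    result = analyze_panel(prepped, config).result
    result.scenario = scenario.name
    return result


def collate_scenarios(results: list[MSMResult]) -> pd.DataFrame:
    """One row per scenario: interaction coefficient, CI, excess years, n."""
    if not results:
        raise ValueError("need at least one result to collate")
    rows = []
    for r in results:
        try:
            excess = r.excess_years_per_decade
        except ZeroDivisionError:
            excess = np.nan
        ci = r.ci.get("interaction") if r.ci else (np.nan, np.nan)
        rows.append(
            {
                "scenario": r.scenario or "base",
                "is_base": (r.scenario or "base") == "base",
                "beta_exposure": r.beta_exposure,
                "beta_time": r.beta_time,
                "beta_interaction": r.beta_interaction,
                "ci_lower": ci[0],
                "ci_upper": ci[1],
                "excess_years_per_decade": excess,
                "n_obs": r.n_obs,
                "n_persons": r.n_persons,
            }
        )
    return pd.DataFrame(rows)
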