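"""End-to-end analysis: prep -> weights -> growth fit (-> bootstrap).

``analyze_panel`` is the single entry point used by the CLI, the
sensitivity scenarios and the bootstrap; it accepts an analysis-ready
panel and returns the fitted result together with the weight and balance
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .engine import (
    CorePipelineConfig,
    CoreResult,
    PanelArrays,
    panel_to_arrays,
    run_core_pipeline,
)
from .growth import GrowthModelSpec, MSMResult, fit_weighted_growth_model
from .weights import BalanceReport, FinalWeights, WeightModelSpec, balance_report

__all__ = ["AnalysisConfig", "AnalysisOutput", "analyze_panel", "analyze_arrays"]


@dataclass(frozen=True)
class AnalysisConfig:
    weight_spec: WeightModelSpec = WeightModelSpec()
    percentiles: tuple[float, float] = (1.0, 99.0)
    truncation_mode: str = "cap"
    growth_spec: GrowthModelSpec = GrowthModelSpec()
    freeze_health_in_treatment: bool = False

    def core_config(self) -> CorePipelineConfig:
        return CorePipelineConfig(
            percentiles=self.percentiles,
            truncation_mode=self.truncation_mode,
            numerator_includes_v=self.weight_spec.numerator_includes_v,
            freeze_health_in_treatment=self.freeze_health_in_treatment,
            pooled_waves=not self.weight_spec.per_wave,
        )


@dataclass
class AnalysisOutput:
    result: MSMResult
    weights: FinalWeights
    core: CoreResult
    arrays: PanelArrays
    balance: list[BalanceReport] = field(default_factory=list)


def analyze_arrays(arrays: PanelArrays, config: AnalysisConfig = AnalysisConfig()) -> AnalysisOutput:
    """Run weighting and the growth fit on an array view of the panel."""
    core = run_core_pipeline(arrays, config.core_config())
    if config.growth_spec.estimator == "weighted_gls_independence" and not (
        config.growth_spec.include_quadratic_time
    ):
        # the core WLS fit already is the independence estimator
        beta = core.beta
        result = MSMResult(
            beta_intercept=float(beta[0]),
            beta_exposure=float(beta[1]),
            beta_time=float(beta[2]),
            beta_interaction=float(beta[3]),
            estimator_used="weighted_gls_independence",
            n_obs=core.n_obs,
            n_persons=int(arrays.n),
        )
    else:
        result = fit_weighted_growth_model(arrays, core.w_final, config.growth_spec)
    person, wave = np.nonzero(arrays.active & np.isfinite(core.w_cum))
    table = pd.DataFrame(
        {
            schema.ID: arrays.ids[person],
            schema.WAVE: wave,
            "sw_treat": core.sw_treat[person, wave],
            "sw_cens": core.sw_cens[person, wave],
            "w_cum": core.w_cum[person, wave],
            "w_final": core.w_final[person, wave],
        }
    )
    weights = FinalWeights(
        table=table,
        truncation_bounds=core.bounds,
        mode=config.truncation_mode,
        n_excluded=core.n_excluded,
    )
    return AnalysisOutput(result=result, weights=weights, core=core, arrays=arrays)


def analyze_panel(
    panel: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    with_balance: bool = False,
) -> AnalysisOutput:
    """Run the analysis on an analysis-ready (prepped) panel DataFrame."""
    arrays = panel_to_arrays(
        panel,
        v_cols=list(config.weight_spec.baseline_covariates),
        l_cols=list(config.weight_spec.timevarying_covariates),
    )
    out = analyze_arrays(arrays, config)
    if with_balance:
        out.balance = [
            balance_report(panel, out.weights, config.weight_spec, t)
            for t in range(1, arrays.n_waves)
        ]
    return out
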