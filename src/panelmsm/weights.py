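"""Per-wave propensity models, stabilized weights, truncation and balance.

Panel-facing wrappers around :mod:`panelmsm.engine`.  One logistic model is
fitted per wave (t >= 1) and per target (exposure or censoring): the
denominator conditions on baseline covariates, lag-1 time-varying
covariates and lag-1 exposure; the stabilizing numerator conditions on
lag-1 exposure only (optionally also baseline covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .engine import (
    PanelArrays,
    PositivityError,
    baseline_exposure_fit,
    censoring_wave_fit,
    exposure_wave_fit,
    panel_to_arrays,
    truncate_weights,
    cumulative_weights,
)

__all__ = [
    "WeightModelSpec",
    "PropensityFit",
    "WaveWeights",
    "FinalWeights",
    "BalanceReport",
    "fit_propensity",
    "stabilized_weights",
    "cumulate_and_truncate",
    "compute_all_weights",
    "balance_report",
    "PositivityError",
]

EXPOSURE_PREV = "exposure_prev"


@dataclass(frozen=True)
class WeightModelSpec:
    """Covariate sets for the weight models.

    ``denominator_covariates`` lists baseline covariates plus the *names* of
    time-varying covariates whose lag-1 values enter the denominator;
    lag-1 exposure is always included in both models.
    """

    baseline_covariates: tuple[str, ...] = tuple(schema.BASELINE_COVARIATES)
    timevarying_covariates: tuple[str, ...] = tuple(schema.MODEL_TIMEVARYING)
    numerator_includes_v: bool = False
    per_wave: bool = True

    @property
    def denominator_covariates(self) -> list[str]:
        return [EXPOSURE_PREV, *self.baseline_covariates, *self.timevarying_covariates]

    @property
    def numerator_covariates(self) -> list[str]:
        if self.numerator_includes_v:
            return [EXPOSURE_PREV, *self.baseline_covariates]
        return [EXPOSURE_PREV]

    def __post_init__(self) -> None:
        num = set(self.numerator_covariates)
        den = set(self.denominator_covariates)
        if not num <= den:
            raise ValueError("numerator covariates must be a subset of denominator covariates")


@dataclass
class PropensityFit:
    """One fitted per-wave logistic model (numerator or denominator)."""

    wave: int
    target: str  # "exposure" | "censoring"
    role: str  # "numerator" | "denominator"
    coefficients: dict[str, float]
    fitted_probabilities: pd.Series  # indexed by person_id, at-risk set only
    n_used: int
    convergence: bool


@dataclass
class WaveWeights:
    """Stabilized per-wave weights for one target at one wave."""

    wave: int
    target: str
    sw: pd.Series  # indexed by person_id; defined only while at risk


@dataclass
class FinalWeights:
    """Cumulative products of stabilized weights after truncation."""

    table: pd.DataFrame  # person_id, wave, w_cum, w_final
    truncation_bounds: tuple[float, float]
    mode: str
    n_excluded: int = 0

    def as_array(self, arrays: PanelArrays) -> np.ndarray:
        out = np.full((arrays.n, arrays.n_waves), np.nan)
        pos = {pid: i for i, pid in enumerate(arrays.ids)}
        rows = self.table[schema.ID].map(pos).to_numpy()
        out[rows, self.table[schema.WAVE].to_numpy(dtype=int)] = self.table[
            "w_final"
        ].to_numpy(dtype=float)
        return out


@dataclass
class BalanceReport:
    """Standardized mean differences and propensity summaries at one wave."""

    wave: int
    smd: pd.DataFrame  # covariate, smd_unweighted, smd_weighted
    propensity_summary: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def max_smd_unweighted(self) -> float:
        return float(self.smd["smd_unweighted"].abs().max())

    @property
    def max_smd_weighted(self) -> float:
        return float(self.smd["smd_weighted"].abs().max())


def _coef_names(spec: WeightModelSpec, role: str) -> list[str]:
    if role == "denominator":
        return ["intercept", EXPOSURE_PREV, *spec.baseline_covariates, *spec.timevarying_covariates]
    if spec.numerator_includes_v:
        return ["intercept", EXPOSURE_PREV, *spec.baseline_covariates]
    return ["intercept", EXPOSURE_PREV]


def _as_arrays(panel_or_arrays, spec: WeightModelSpec) -> PanelArrays:
    if isinstance(panel_or_arrays, PanelArrays):
        return panel_or_arrays
    return panel_to_arrays(
        panel_or_arrays,
        v_cols=list(spec.baseline_covariates),
        l_cols=list(spec.timevarying_covariates),
    )


def fit_propensity(
    panel, spec: WeightModelSpec, wave: int, target: str = "exposure"
) -> tuple[PropensityFit, PropensityFit]:
    """Fit the (numerator, denominator) logistic models at one wave.

    Returns both fits; each carries named coefficients, fitted
    probabilities over the at-risk set, the risk-set size and a convergence
    flag (false under quasi-complete separation).
    """
    if target not in ("exposure", "censoring"):
        raise ValueError(f"target must be 'exposure' or 'censoring', got {target!r}")
    arrays = _as_arrays(panel, spec)
    fitter = exposure_wave_fit if target == "exposure" else censoring_wave_fit
    kwargs = {"numerator_includes_v": spec.numerator_includes_v}
    wf = fitter(arrays, wave, **kwargs)
    out = []
    for role, fit in (("numerator", wf.num_fit), ("denominator", wf.den_fit)):
        names = _coef_names(spec, role)
        x = _model_matrix(arrays, wave, spec, role)
        probs = pd.Series(fit.predict(x[wf.risk]), index=arrays.ids[wf.risk], name="p")
        out.append(
            PropensityFit(
                wave=wave,
                target=target,
                role=role,
                coefficients=dict(zip(names, fit.coef)),
                fitted_probabilities=probs,
                n_used=fit.n_obs,
                convergence=fit.converged,
            )
        )
    return tuple(out)


def _model_matrix(arrays: PanelArrays, t: int, spec: WeightModelSpec, role: str) -> np.ndarray:
    a_prev = arrays.A[:, t - 1]
    if role == "denominator":
        return np.column_stack([np.ones(arrays.n), a_prev, arrays.V, arrays.L[:, t - 1, :]])
    if spec.numerator_includes_v:
        return np.column_stack([np.ones(arrays.n), a_prev, arrays.V])
    return np.column_stack([np.ones(arrays.n), a_prev])


def stabilized_weights(panel, num_fit: PropensityFit, den_fit: PropensityFit) -> WaveWeights:
    """Form stabilized weights from matched numerator/denominator fits.

    Exposed person-waves get ``p_num / p_den``; unexposed get
    ``(1 - p_num) / (1 - p_den)``.  Censoring weights use the probability of
    remaining uncensored in both numerator and denominator, so the same
    ratio formula applies with the "uncensored" event.
    """
    if (num_fit.wave, num_fit.target) != (den_fit.wave, den_fit.target):
        raise ValueError("numerator and denominator fits are for different waves/targets")
    wave, target = den_fit.wave, den_fit.target
    p_num = num_fit.fitted_probabilities
    p_den = den_fit.fitted_probabilities.reindex(p_num.index)
    if ((p_den <= 0.0) | (p_den >= 1.0)).any():
        raise PositivityError(f"positivity violation in {target} model at wave {wave}")
    if target == "exposure":
        w0 = panel.loc[panel[schema.WAVE] == wave].set_index(schema.ID)
        a = w0[schema.EXPOSURE].reindex(p_num.index)
        sw = np.where(a == 1.0, p_num / p_den, (1.0 - p_num) / (1.0 - p_den))
    else:
        sw = ((1.0 - p_num) / (1.0 - p_den)).to_numpy()
    return WaveWeights(wave=wave, target=target, sw=pd.Series(sw, index=p_num.index, name="sw"))


def cumulate_and_truncate(
    panel,
    wave_weights: list[WaveWeights] | None = None,
    percentiles: tuple[float, float] = (1.0, 99.0),
    mode: str = "cap",
    spec: WeightModelSpec | None = None,
) -> FinalWeights:
    """Cumulate per-wave stabilized weights and truncate the pooled product.

    If ``wave_weights`` is None the per-wave fits are computed here.  Bounds
    come from the pooled distribution of all person-wave cumulative weights
    (linear percentile interpolation); ``cap`` clamps, ``exclude`` drops
    person-waves outside the bounds.
    """
    spec = spec or WeightModelSpec()
    arrays = _as_arrays(panel, spec)
    n, t_max = arrays.n, arrays.n_waves
    sw_treat = np.full((n, t_max), np.nan)
    sw_cens = np.full((n, t_max), np.nan)
    sw_treat[:, 0] = np.where(arrays.active[:, 0], 1.0, np.nan)
    sw_cens[:, 0] = sw_treat[:, 0]
    pos = {pid: i for i, pid in enumerate(arrays.ids)}
    if wave_weights is None:
        sw_treat[:, 0] = baseline_exposure_fit(arrays).sw
        for t in range(1, t_max):
            sw_treat[:, t] = exposure_wave_fit(
                arrays, t, numerator_includes_v=spec.numerator_includes_v
            ).sw
            sw_cens[:, t] = censoring_wave_fit(
                arrays, t, numerator_includes_v=spec.numerator_includes_v
            ).sw
    else:
        for ww in wave_weights:
            rows = ww.sw.index.map(pos).to_numpy()
            tgt = sw_treat if ww.target == "exposure" else sw_cens
            tgt[rows, ww.wave] = ww.sw.to_numpy()
    w_cum = cumulative_weights(arrays, sw_treat, sw_cens)
    valid = arrays.active & np.isfinite(w_cum)
    if int(valid.sum()) < 100:
        warnings.warn(
            f"only {int(valid.sum())} person-wave weights: percentile bounds unreliable"
        )
    w_final, bounds, n_excluded = truncate_weights(w_cum, valid, percentiles, mode)
    person, wave = np.nonzero(valid)
    table = pd.DataFrame(
        {
            schema.ID: arrays.ids[person],
            schema.WAVE: wave,
            "sw_treat": sw_treat[person, wave],
            "sw_cens": sw_cens[person, wave],
            "w_cum": w_cum[person, wave],
            "w_final": w_final[person, wave],
        }
    )
    return FinalWeights(table=table, truncation_bounds=bounds, mode=mode, n_excluded=n_excluded)


# keep an explicit alias: the full per-wave computation is what the pipeline calls
compute_all_weights = cumulate_and_truncate


def _smd_one(x: np.ndarray, a: np.ndarray, w: np.ndarray | None) -> float:
    """(weighted) standardized mean difference of x between a==1 and a==0."""
    if w is None:
        w = np.ones_like(x)
    m1 = np.average(x[a == 1], weights=w[a == 1])
    m0 = np.average(x[a == 0], weights=w[a == 0])
    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary:
        pooled = np.sqrt((m1 * (1 - m1) + m0 * (1 - m0)) / 2.0)
    else:
        v1 = np.average((x[a == 1] - m1) ** 2, weights=w[a == 1])
        v0 = np.average((x[a == 0] - m0) ** 2, weights=w[a == 0])
        pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0:
        return 0.0
    return float((m1 - m0) / pooled)


def balance_report(
    panel, weights: FinalWeights, spec: WeightModelSpec, wave: int
) -> BalanceReport:
    """Per-covariate SMDs (unweighted and weighted by w_final) between the
    wave-``wave`` exposure groups, plus fitted-propensity density summaries.

    Covariates are the denominator set: baseline covariates and lag-1
    time-varying covariates.
    """
    arrays = _as_arrays(panel, spec)
    w_arr = weights.as_array(arrays)
    a = arrays.A[:, wave]
    mask = arrays.active[:, wave] & np.isfinite(a) & np.isfinite(w_arr[:, wave])
    flags = []
    if wave >= 1:
        mask &= np.isfinite(arrays.L[:, wave - 1, :]).all(axis=1)
    a = a[mask]
    w = w_arr[mask, wave]
    if len(np.unique(a)) < 2:
        return BalanceReport(
            wave=wave,
            smd=pd.DataFrame(columns=["covariate", "smd_unweighted", "smd_weighted"]),
            propensity_summary=pd.DataFrame(),
            flags=["single-group wave: SMD undefined"],
        )
    rows = []
    covs = {name: arrays.V[mask, j] for j, name in enumerate(arrays.v_names)}
    if wave >= 1:
        # lag-1 exposure is intentionally left out: the stabilizing numerator
        # conditions on it, so weighting does not (and should not) balance it
        for j, name in enumerate(arrays.l_names):
            covs[f"{name}_lag1"] = arrays.L[mask, wave - 1, j]
    for name, x in covs.items():
        ok = np.isfinite(x)
        rows.append(
            {
                "covariate": name,
                "smd_unweighted": _smd_one(x[ok], a[ok], None),
                "smd_weighted": _smd_one(x[ok], a[ok], w[ok]),
            }
        )
    smd = pd.DataFrame(rows)

    if wave >= 1:
        _, den_fit = fit_propensity(panel, spec, wave, "exposure")
        p = den_fit.fitted_probabilities
        w0 = panel.loc[panel[schema.WAVE] == wave].set_index(schema.ID)
        a_ser = w0[schema.EXPOSURE].reindex(p.index)
        summ = (
            pd.DataFrame({"p": p, "group": a_ser})
            .groupby("group")["p"]
            .describe(percentiles=[0.05, 0.25, 0.5, 0.75, 0.95])
            .reset_index()
        )
    else:
        summ = pd.DataFrame()
    return BalanceReport(wave=wave, smd=smd, propensity_summary=summ, flags=flags)
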