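"""Array-level numerical core shared by the weighting engine and bootstrap.

Everything here works on dense ``[n_persons, n_waves]`` numpy arrays so the
full pipeline (per-wave propensity fits, stabilized weights, cumulation,
truncation, weighted growth fit) can be re-run tens of thousands of times
inside the bootstrap within a desk-scale budget.  The pandas-facing modules
wrap these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg.lapack import dposv
from scipy.special import expit

from . import schema
from .schema import ACTIVE, DEAD, LOST

_ETA_MAX = 30.0


class PositivityError(RuntimeError):
    """A fitted denominator probability of exactly 0 or 1."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    converged: bool
    n_obs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.clip(X @ self.coef, -_ETA_MAX, _ETA_MAX))


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    # 2 * sum(log(1 + exp(eta)) - y*eta), computed overflow-safe
    return 2.0 * float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0.0) - y * eta))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
    check_deviance: bool = True,
) -> LogisticFit:
    """Unpenalized maximum-likelihood logistic regression via Newton/IRLS.

    ``beta0`` warm-starts the iterations (used heavily inside the
    bootstrap).  Flags ``converged=False`` under quasi-complete separation
    (diverging coefficients) or a degenerate outcome.  Matches brute-force
    likelihood maximization to well below 1e-6 on small problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("empty risk set: no observations to fit")
    ymean = y.mean()
    if ymean in (0.0, 1.0):
        beta = np.zeros(p)
        beta[0] = _ETA_MAX if ymean == 1.0 else -_ETA_MAX
        return LogisticFit(coef=beta, converged=False, n_obs=n)

    if beta0 is not None and beta0.shape == (p,):
        beta = beta0.astype(float, copy=True)
    else:
        beta = np.zeros(p)
        beta[0] = np.log(ymean / (1.0 - ymean))  # assumes X[:, 0] is the intercept
    eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
    dev = _deviance(eta, y) if check_deviance else np.inf
    ridge = 1e-10 * np.eye(p)
    Xt = X.T
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = Xt @ (y - mu)
        hess = (X * w[:, None]).T @ X
        _, step, info = dposv(hess + ridge, grad, lower=1, overwrite_a=True, overwrite_b=False)
        if info != 0:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        if check_deviance:
            # step-halving on deviance increase
            for _ in range(12):
                cand = beta + step
                eta_c = np.clip(X @ cand, -_ETA_MAX, _ETA_MAX)
                dev_c = _deviance(eta_c, y)
                if dev_c <= dev + 1e-9:
                    break
                step = step / 2.0
            dev = dev_c
            beta, eta = cand, eta_c
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        else:
            smax = float(np.max(np.abs(step)))
            if smax > 4.0:  # damp runaway (separation) steps
                step *= 4.0 / smax
                smax = 4.0
            beta = beta + step
            eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
            if smax < tol:
                converged = True
                break
    if np.max(np.abs(beta)) > 25.0:
        converged = False
    return LogisticFit(coef=beta, converged=converged, n_obs=n)


# ---------------------------------------------------------------------------
# panel <-> array conversion


@dataclass
class PanelArrays:
    """Wide-array view of an analysis-ready panel."""

    ids: np.ndarray  # [n] person ids
    A: np.ndarray  # [n, T] exposure (nan off support)
    Y: np.ndarray  # [n, T] outcome
    active: np.ndarray  # [n, T] bool: alive and under observation
    lost_at: np.ndarray  # [n, T] bool: first wave lost
    dead_at: np.ndarray  # [n, T] bool: first wave dead
    V: np.ndarray  # [n, p_v] baseline covariates
    L: np.ndarray  # [n, T, p_l] time-varying covariates
    v_names: list[str]
    l_names: list[str]
    time: np.ndarray  # [T] years since baseline

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_waves(self) -> int:
        return self.A.shape[1]

    def take(self, idx: np.ndarray) -> "PanelArrays":
        """Row-resample persons (bootstrap); duplicates allowed."""
        return PanelArrays(
            ids=self.ids[idx],
            A=self.A[idx],
            Y=self.Y[idx],
            active=self.active[idx],
            lost_at=self.lost_at[idx],
            dead_at=self.dead_at[idx],
            V=self.V[idx],
            L=self.L[idx],
            v_names=self.v_names,
            l_names=self.l_names,
            time=self.time,
        )


def panel_to_arrays(panel, v_cols=None, l_cols=None) -> PanelArrays:
    """Convert a long panel DataFrame into :class:`PanelArrays`."""
    v_cols = list(v_cols) if v_cols is not None else list(schema.BASELINE_COVARIATES)
    l_cols = list(l_cols) if l_cols is not None else list(schema.MODEL_TIMEVARYING)
    df = panel.sort_values([schema.ID, schema.WAVE])
    ids, inv = np.unique(df[schema.ID].to_numpy(), return_inverse=True)
    n = len(ids)
    t_max = int(df[schema.WAVE].max()) + 1
    wave = df[schema.WAVE].to_numpy(dtype=int)

    def wide(col, fill=np.nan):
        out = np.full((n, t_max), fill)
        out[inv, wave] = df[col].to_numpy(dtype=float)
        return out

    status = np.full((n, t_max), "", dtype=object)
    status[inv, wave] = df[schema.STATUS].to_numpy()
    active = status == ACTIVE
    lost_at = status == LOST
    dead_at = status == DEAD

    w0 = df.loc[df[schema.WAVE] == 0]
    v_by_id = {pid: row for pid, row in zip(w0[schema.ID].to_numpy(), w0[v_cols].to_numpy(dtype=float))}
    V = np.vstack([v_by_id[pid] for pid in ids])
    L = np.stack([wide(c) for c in l_cols], axis=2)
    time = np.arange(t_max) * schema.YEARS_PER_WAVE
    return PanelArrays(
        ids=ids,
        A=wide(schema.EXPOSURE),
        Y=wide(schema.OUTCOME),
        active=active,
        lost_at=lost_at,
        dead_at=dead_at,
        V=V,
        L=L,
        v_names=v_cols,
        l_names=l_cols,
        time=time,
    )


# ---------------------------------------------------------------------------
# per-wave weight machinery


@dataclass
class WaveFitResult:
    wave: int
    target: str  # "exposure" | "censoring"
    num_fit: LogisticFit
    den_fit: LogisticFit
    sw: np.ndarray  # [n] stabilized weight, nan off risk set
    risk: np.ndarray  # [n] bool risk-set membership


def _design(arrays: PanelArrays, t: int, l_source: np.ndarray) -> np.ndarray:
    """Denominator design at wave t: [1, A_{t-1}, V, L_{t-1}]."""
    a_prev = arrays.A[:, t - 1]
    return np.column_stack([np.ones(arrays.n), a_prev, arrays.V, l_source[:, t - 1, :]])


def exposure_wave_fit(
    arrays: PanelArrays,
    t: int,
    l_source: np.ndarray | None = None,
    numerator_includes_v: bool = False,
    warm: "WaveFitResult | None" = None,
    fit_kw: dict | None = None,
) -> WaveFitResult:
    """Fit numerator/denominator propensity models for exposure at wave t>=1
    and return stabilized treatment weights on the at-risk set."""
    if t < 1:
        raise ValueError("propensity models are defined for waves >= 1")
    fit_kw = fit_kw or {}
    L = l_source if l_source is not None else arrays.L
    x_den = _design(arrays, t, L)
    x_num = (
        np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1], arrays.V])
        if numerator_includes_v
        else np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1]])
    )
    risk = (
        arrays.active[:, t]
        & arrays.active[:, t - 1]
        & np.isfinite(arrays.A[:, t])
        & np.isfinite(x_den).all(axis=1)
    )
    if not risk.any():
        raise ValueError(f"empty exposure risk set at wave {t}")
    a_t = arrays.A[risk, t]
    den = fit_logistic(x_den[risk], a_t, beta0=warm.den_fit.coef if warm else None, **fit_kw)
    num = fit_logistic(x_num[risk], a_t, beta0=warm.num_fit.coef if warm else None, **fit_kw)
    p_den = den.predict(x_den[risk])
    p_num = num.predict(x_num[risk])
    if np.any((p_den <= 0.0) | (p_den >= 1.0)):
        raise PositivityError(f"exposure propensity of exactly 0 or 1 at wave {t}")
    sw = np.full(arrays.n, np.nan)
    sw[risk] = np.where(a_t == 1.0, p_num / p_den, (1.0 - p_num) / (1.0 - p_den))
    return WaveFitResult(wave=t, target="exposure", num_fit=num, den_fit=den, sw=sw, risk=risk)


def baseline_exposure_fit(
    arrays: PanelArrays,
    l_source: np.ndarray | None = None,
    warm: "WaveFitResult | None" = None,
    fit_kw: dict | None = None,
) -> WaveFitResult:
    """Stabilized weight for baseline exposure: marginal P(A_0) over
    P(A_0 | V, L_0).  Without it, baseline exposure-covariate association
    (which later transition weights progressively remove) would leave a
    spurious time trend in the weighted exposure-outcome association."""
    fit_kw = fit_kw or {}
    L = l_source if l_source is not None else arrays.L
    x_den = np.column_stack([np.ones(arrays.n), arrays.V, L[:, 0, :]])
    risk = arrays.active[:, 0] & np.isfinite(arrays.A[:, 0]) & np.isfinite(x_den).all(axis=1)
    if not risk.any():
        raise ValueError("empty baseline risk set")
    a0 = arrays.A[risk, 0]
    den = fit_logistic(x_den[risk], a0, beta0=warm.den_fit.coef if warm else None, **fit_kw)
    num = fit_logistic(np.ones((int(risk.sum()), 1)), a0)
    p_den = den.predict(x_den[risk])
    p_num = num.predict(np.ones((int(risk.sum()), 1)))
    if np.any((p_den <= 0.0) | (p_den >= 1.0)):
        raise PositivityError("exposure propensity of exactly 0 or 1 at wave 0")
    sw = np.full(arrays.n, np.nan)
    sw[risk] = np.where(a0 == 1.0, p_num / p_den, (1.0 - p_num) / (1.0 - p_den))
    return WaveFitResult(wave=0, target="exposure", num_fit=num, den_fit=den, sw=sw, risk=risk)


def censoring_wave_fit(
    arrays: PanelArrays,
    t: int,
    numerator_includes_v: bool = False,
    warm: "WaveFitResult | None" = None,
    fit_kw: dict | None = None,
) -> WaveFitResult:
    """Fit censoring models at wave t>=1: risk set is persons under
    observation at t-1 and not dead at t (death is a competing event, never
    treated as censoring); outcome is being lost at t.  Stabilized weights
    are the ratio of numerator to denominator probabilities of remaining
    uncensored, assigned to those who remain under observation."""
    if t < 1:
        raise ValueError("censoring models are defined for waves >= 1")
    fit_kw = fit_kw or {}
    x_den = _design(arrays, t, arrays.L)
    x_num = (
        np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1], arrays.V])
        if numerator_includes_v
        else np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1]])
    )
    risk = (
        arrays.active[:, t - 1]
        & ~arrays.dead_at[:, t]
        & (arrays.active[:, t] | arrays.lost_at[:, t])
        & np.isfinite(x_den).all(axis=1)
    )
    if not risk.any():
        raise ValueError(f"empty censoring risk set at wave {t}")
    c_t = arrays.lost_at[risk, t].astype(float)
    den = fit_logistic(x_den[risk], c_t, beta0=warm.den_fit.coef if warm else None, **fit_kw)
    num = fit_logistic(x_num[risk], c_t, beta0=warm.num_fit.coef if warm else None, **fit_kw)
    p_den = 1.0 - den.predict(x_den[risk])  # P(remain uncensored)
    p_num = 1.0 - num.predict(x_num[risk])
    if np.any((p_den <= 0.0) | (p_den >= 1.0)):
        raise PositivityError(f"censoring probability of exactly 0 or 1 at wave {t}")
    sw = np.full(arrays.n, np.nan)
    uncensored = risk & arrays.active[:, t]
    ratio = p_num / p_den
    full_ratio = np.full(arrays.n, np.nan)
    full_ratio[risk] = ratio
    sw[uncensored] = full_ratio[uncensored]
    return WaveFitResult(wave=t, target="censoring", num_fit=num, den_fit=den, sw=sw, risk=risk)


def pooled_wave_fits(
    arrays: PanelArrays,
    target: str = "exposure",
    l_source: np.ndarray | None = None,
    numerator_includes_v: bool = False,
) -> list[WaveFitResult]:
    """Pooled alternative to the per-wave fits for tiny samples: one
    logistic model over all post-baseline person-waves with wave-indicator
    dummies (base wave 1), sharing covariate coefficients across waves."""
    if target not in ("exposure", "censoring"):
        raise ValueError(f"unknown target {target!r}")
    t_max = arrays.n_waves
    L = l_source if l_source is not None else arrays.L
    risks, dens, nums, ys = [], [], [], []
    for t in range(1, t_max):
        x_den = _design(arrays, t, L if target == "exposure" else arrays.L)
        if target == "exposure":
            risk = (
                arrays.active[:, t]
                & arrays.active[:, t - 1]
                & np.isfinite(arrays.A[:, t])
                & np.isfinite(x_den).all(axis=1)
            )
            y = arrays.A[:, t]
        else:
            risk = (
                arrays.active[:, t - 1]
                & ~arrays.dead_at[:, t]
                & (arrays.active[:, t] | arrays.lost_at[:, t])
                & np.isfinite(x_den).all(axis=1)
            )
            y = arrays.lost_at[:, t].astype(float)
        dummies = np.zeros((arrays.n, t_max - 2))
        if t >= 2:
            dummies[:, t - 2] = 1.0
        x_num = (
            np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1], arrays.V, dummies])
            if numerator_includes_v
            else np.column_stack([np.ones(arrays.n), arrays.A[:, t - 1], dummies])
        )
        risks.append(risk)
        dens.append(np.column_stack([x_den, dummies])[risk])
        nums.append(x_num[risk])
        ys.append(y[risk])
    den = fit_logistic(np.vstack(dens), np.concatenate(ys))
    num = fit_logistic(np.vstack(nums), np.concatenate(ys))
    out = []
    for t, risk in zip(range(1, t_max), risks):
        p_den = den.predict(dens[t - 1])
        p_num = num.predict(nums[t - 1])
        if np.any((p_den <= 0.0) | (p_den >= 1.0)):
            raise PositivityError(f"pooled {target} probability of exactly 0 or 1 at wave {t}")
        sw = np.full(arrays.n, np.nan)
        if target == "exposure":
            a_t = arrays.A[risk, t]
            sw[risk] = np.where(a_t == 1.0, p_num / p_den, (1.0 - p_num) / (1.0 - p_den))
        else:
            ratio = (1.0 - p_num) / (1.0 - p_den)
            full = np.full(arrays.n, np.nan)
            full[risk] = ratio
            keep = risk & arrays.active[:, t]
            sw[keep] = full[keep]
        out.append(
            WaveFitResult(wave=t, target=target, num_fit=num, den_fit=den, sw=sw, risk=risk)
        )
    return out


def cumulative_weights(
    arrays: PanelArrays,
    sw_treat: np.ndarray,
    sw_cens: np.ndarray,
) -> np.ndarray:
    """Running product of per-wave stabilized weights; wave 0 carries 1."""
    m = sw_treat * sw_cens
    return np.cumprod(m, axis=1)


def truncate_weights(
    w_cum: np.ndarray,
    valid: np.ndarray,
    percentiles: tuple[float, float] = (1.0, 99.0),
    mode: str = "cap",
) -> tuple[np.ndarray, tuple[float, float], int]:
    """Truncate pooled cumulative weights at the given percentiles.

    Bounds come from the pooled distribution of all valid person-wave
    weights (linear interpolation between order statistics).  ``cap`` clamps
    to the bounds; ``exclude`` drops person-waves outside them.  Returns the
    final weights, the bounds, and the number of excluded person-waves.
    """
    if mode not in ("cap", "exclude"):
        raise ValueError(f"unknown truncation mode: {mode!r}")
    pool = w_cum[valid & np.isfinite(w_cum)]
    if pool.size == 0:
        raise ValueError("no valid person-wave weights to truncate")
    lo, hi = np.percentile(pool, percentiles)
    w_final = w_cum.copy()
    n_excluded = 0
    if mode == "cap":
        w_final = np.clip(w_final, lo, hi)
    else:
        outside = valid & np.isfinite(w_cum) & ((w_cum < lo) | (w_cum > hi))
        n_excluded = int(outside.sum())
        w_final[outside] = np.nan
    return w_final, (float(lo), float(hi)), n_excluded


# ---------------------------------------------------------------------------
# growth model (working-independence WLS; the mixed estimator lives in growth.py)


def growth_rows(arrays: PanelArrays, w_final: np.ndarray):
    """Design, outcome and weights for person-waves contributing to the fit."""
    mask = arrays.active & np.isfinite(arrays.Y) & np.isfinite(w_final) & np.isfinite(arrays.A)
    person, wave = np.nonzero(mask)
    t = arrays.time[wave]
    a = arrays.A[person, wave]
    X = np.column_stack([np.ones(person.size), a, t, a * t])
    return X, arrays.Y[person, wave], w_final[person, wave], person


def wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    xtw = X.T * w
    beta = np.linalg.solve(xtw @ X, xtw @ y)
    return beta


@dataclass
class CorePipelineConfig:
    """Knobs for one array-level pipeline run."""

    percentiles: tuple[float, float] = (1.0, 99.0)
    truncation_mode: str = "cap"
    numerator_includes_v: bool = False
    freeze_health_in_treatment: bool = False
    weight_baseline: bool = True
    pooled_waves: bool = False  # one model with wave dummies (tiny samples)


@dataclass
class CoreResult:
    beta: np.ndarray  # [intercept, exposure, time, exposure x time]
    w_final: np.ndarray
    w_cum: np.ndarray
    sw_treat: np.ndarray
    sw_cens: np.ndarray
    bounds: tuple[float, float]
    n_excluded: int
    exposure_fits: list
    censoring_fits: list
    n_obs: int


def frozen_health_l(arrays: PanelArrays, health_names=None) -> np.ndarray:
    """Copy of L with health covariates held at their wave-0 values."""
    health_names = health_names if health_names is not None else schema.HEALTH_COVARIATES
    L = arrays.L.copy()
    for j, name in enumerate(arrays.l_names):
        if name in health_names:
            L[:, :, j] = L[:, [0], j]
    return L


def run_core_pipeline(
    arrays: PanelArrays,
    config: CorePipelineConfig | None = None,
    warm: "CoreResult | None" = None,
) -> CoreResult:
    """Weights + working-independence growth fit in one pass over arrays.

    ``warm`` (a previous full-sample result) warm-starts every logistic fit
    at its full-sample coefficients — a large speedup inside the bootstrap.
    """
    config = config or CorePipelineConfig()
    n, t_max = arrays.n, arrays.n_waves
    sw_treat = np.full((n, t_max), np.nan)
    sw_cens = np.full((n, t_max), np.nan)
    sw_cens[:, 0] = np.where(arrays.active[:, 0], 1.0, np.nan)
    l_treat = frozen_health_l(arrays) if config.freeze_health_in_treatment else None
    # warm-started replicate fits tolerate a looser, cheaper Newton
    fit_kw = {"tol": 1e-6, "max_iter": 12, "check_deviance": False} if warm else {}
    e_fits, c_fits = [], []
    if config.weight_baseline:
        bf = baseline_exposure_fit(
            arrays, l_source=l_treat, warm=warm.exposure_fits[0] if warm else None, fit_kw=fit_kw
        )
        sw_treat[:, 0] = bf.sw
        e_fits.append(bf)
    else:
        sw_treat[:, 0] = np.where(arrays.active[:, 0], 1.0, np.nan)
    off = 1 if config.weight_baseline else 0
    if config.pooled_waves:
        e_pooled = pooled_wave_fits(
            arrays, "exposure", l_source=l_treat,
            numerator_includes_v=config.numerator_includes_v,
        )
        c_pooled = pooled_wave_fits(
            arrays, "censoring", numerator_includes_v=config.numerator_includes_v
        )
        for ef, cf in zip(e_pooled, c_pooled):
            sw_treat[:, ef.wave] = ef.sw
            sw_cens[:, cf.wave] = cf.sw
        e_fits.extend(e_pooled)
        c_fits.extend(c_pooled)
    else:
        for t in range(1, t_max):
            ef = exposure_wave_fit(
                arrays,
                t,
                l_source=l_treat,
                numerator_includes_v=config.numerator_includes_v,
                warm=warm.exposure_fits[t - 1 + off] if warm else None,
                fit_kw=fit_kw,
            )
            cf = censoring_wave_fit(
                arrays,
                t,
                numerator_includes_v=config.numerator_includes_v,
                warm=warm.censoring_fits[t - 1] if warm else None,
                fit_kw=fit_kw,
            )
            sw_treat[:, t] = ef.sw
            sw_cens[:, t] = cf.sw
            e_fits.append(ef)
            c_fits.append(cf)
    w_cum = cumulative_weights(arrays, sw_treat, sw_cens)
    valid = arrays.active & np.isfinite(arrays.Y)
    w_final, bounds, n_excluded = truncate_weights(
        w_cum, valid, config.percentiles, config.truncation_mode
    )
    X, y, w, _ = growth_rows(arrays, w_final)
    beta = wls_fit(X, y, w)
    return CoreResult(
        beta=beta,
        w_final=w_final,
        w_cum=w_cum,
        sw_treat=sw_treat,
        sw_cens=sw_cens,
        bounds=bounds,
        n_excluded=n_excluded,
        exposure_fits=e_fits,
        censoring_fits=c_fits,
        n_obs=int(y.size),
    )
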