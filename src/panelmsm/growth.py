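"""IP-weighted growth models and derived summaries.

Two estimators of the marginal mean model
``E[Y] = b0 + b1*A + b2*t + b3*A*t``:

* ``weighted_gls_independence`` — weighted least squares with a working
  independence covariance.  Person-clustered bootstrap provides inference;
  this is the estimator used inside the bootstrap and the coverage study.
* ``weighted_mixed`` — Gaussian maximum likelihood with person random
  effects (intercept, or intercept + slope) and per-observation analytic
  weights entering as inverse residual-variance factors.  Falls back to the
  independence estimator if the variance-component optimization fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import schema
from .engine import PanelArrays, growth_rows, panel_to_arrays, wls_fit

__all__ = [
    "GrowthModelSpec",
    "MSMResult",
    "fit_weighted_growth_model",
    "fit_naive_adjusted",
    "excess_aging_per_decade",
    "predict_regime_trajectories",
]

COEF_NAMES = ("intercept", "exposure", "time", "interaction")


@dataclass(frozen=True)
class GrowthModelSpec:
    estimator: str = "weighted_mixed"  # or "weighted_gls_independence"
    random_effects: str = "slope"  # "slope" (intercept+slope), "intercept", "none"
    include_quadratic_time: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("weighted_mixed", "weighted_gls_independence"):
            raise ValueError(f"unknown estimator: {self.estimator!r}")
        if self.random_effects not in ("slope", "intercept", "none"):
            raise ValueError(f"unknown random_effects: {self.random_effects!r}")


@dataclass
class MSMResult:
    """Fitted growth-model coefficients and derived quantities."""

    beta_intercept: float
    beta_exposure: float
    beta_time: float
    beta_interaction: float
    estimator_used: str
    n_obs: int
    n_persons: int
    converged: bool = True
    beta_quadratic: float | None = None
    ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    scenario: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def excess_years_per_decade(self) -> float:
        return excess_aging_per_decade(self.beta_interaction, self.beta_time)

    def coefficients(self) -> dict[str, float]:
        out = {
            "intercept": self.beta_intercept,
            "exposure": self.beta_exposure,
            "time": self.beta_time,
            "interaction": self.beta_interaction,
        }
        if self.beta_quadratic is not None:
            out["time_squared"] = self.beta_quadratic
        return out

    def to_dict(self) -> dict:
        out = {
            "coefficients": self.coefficients(),
            "estimator": self.estimator_used,
            "n_obs": self.n_obs,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "n_boot": self.n_boot,
            "scenario": self.scenario,
        }
        try:
            out["excess_years_per_decade"] = self.excess_years_per_decade
        except ZeroDivisionError:
            out["excess_years_per_decade"] = None
        if self.ci is not None:
            out["ci_95"] = {k: list(v) for k, v in self.ci.items()}
        return out


def _maybe_quadratic(X: np.ndarray, spec: GrowthModelSpec) -> np.ndarray:
    if spec.include_quadratic_time:
        return np.column_stack([X, X[:, 2] ** 2])
    return X


def _pad_by_person(person: np.ndarray, cols: list[np.ndarray]):
    """Reshape row-wise data into [n_persons, max_obs] arrays padded with 0,
    plus an observation mask.  Zero weight rows drop out of the precision
    algebra naturally."""
    n_person = person.max() + 1
    counts = np.bincount(person, minlength=n_person)
    t_max = counts.max()
    order = np.argsort(person, kind="stable")
    slot = np.concatenate([np.arange(c) for c in counts if c > 0])
    mask = np.zeros((n_person, t_max), dtype=bool)
    mask[person[order], slot] = True
    padded = []
    for col in cols:
        out = np.zeros((n_person, t_max) + col.shape[1:])
        out[person[order], slot] = col[order]
        padded.append(out)
    return padded, mask


def _mixed_loglik(theta, yP, XP, ZP, wP, mask, q):
    """Negative profile log-likelihood (beta profiled out by GLS).

    Marginal covariance per person: V = Z Psi Z' + sigma2 * diag(1/w).
    theta parametrizes log(sigma2) and the log-Cholesky of Psi.
    Woodbury identities keep everything at q x q (q <= 2) per person.
    """
    log_s2 = theta[0]
    s2 = np.exp(log_s2)
    chol = np.zeros((q, q))
    vals = theta[1:]
    # diagonal entries are logged for positivity
    k = 0
    for i in range(q):
        for j in range(i + 1):
            chol[i, j] = np.exp(vals[k]) if i == j else vals[k]
            k += 1
    g = chol @ chol.T  # Psi, the random-effect covariance
    try:
        g_inv = np.linalg.inv(g + 1e-12 * np.eye(q))
    except np.linalg.LinAlgError:
        return 1e300, None
    d = wP / s2  # precision of residuals, 0 at padded slots
    # Woodbury: V^{-1} = D - D Z (Psi^{-1} + Z'DZ)^{-1} Z'D with D = diag(w)/s2
    zd = ZP * d[..., None]
    K = g_inv[None] + np.einsum("ntq,ntr->nqr", zd, ZP)
    K_inv = np.linalg.inv(K)
    sign, logdet_K = np.linalg.slogdet(K)
    if np.any(sign <= 0):
        return 1e300, None
    _, logdet_g = np.linalg.slogdet(g)
    logdet_V = (
        -np.where(mask, np.log(np.maximum(d, 1e-300)), 0.0).sum(axis=1) + logdet_g + logdet_K
    )

    def vinv_dot(M):
        # V^{-1} M per person for M of shape [n, t, m]
        dM = M * d[..., None]
        zdm = np.einsum("ntq,ntm->nqm", ZP, dM)
        corr = np.einsum("ntq,nqr,nrm->ntm", zd, K_inv, zdm)
        return dM - corr

    Xv = vinv_dot(XP)
    xtvx = np.einsum("ntp,ntm->pm", XP, Xv)
    xtvy = np.einsum("ntp,nt->p", XP, vinv_dot(yP[..., None])[..., 0])
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return 1e300, None
    r = yP - np.einsum("ntp,p->nt", XP, beta)
    r = np.where(mask, r, 0.0)
    quad = np.einsum("nt,nt->", r, vinv_dot(r[..., None])[..., 0])
    nll = 0.5 * (logdet_V.sum() + quad + mask.sum() * np.log(2 * np.pi))
    return nll, beta


def _fit_weighted_mixed(X, y, w, person, spec: GrowthModelSpec):
    q = 2 if spec.random_effects == "slope" else 1
    Z = X[:, [0, 2]] if q == 2 else X[:, [0]]
    (yP, XP, ZP, wP), mask = _pad_by_person(person, [y, X, Z, w])
    n_theta = 1 + q * (q + 1) // 2
    x0 = np.zeros(n_theta)
    x0[0] = np.log(max(np.var(y), 1e-6) * 0.5)
    x0[1] = np.log(0.5)
    if q == 2:
        x0[2] = 0.0
        x0[3] = np.log(0.05)

    def obj(theta):
        return _mixed_loglik(theta, yP, XP, ZP, wP, mask, q)[0]

    res = minimize(obj, x0, method="Nelder-Mead", options={"maxiter": 600, "xatol": 1e-6, "fatol": 1e-8})
    nll, beta = _mixed_loglik(res.x, yP, XP, ZP, wP, mask, q)
    if beta is None or not np.all(np.isfinite(beta)):
        raise RuntimeError("variance-component optimization failed")
    return beta, bool(res.success)


def fit_weighted_growth_model(
    panel_or_arrays,
    weights: np.ndarray | pd.DataFrame | None = None,
    spec: GrowthModelSpec = GrowthModelSpec(),
) -> MSMResult:
    """Fit the IP-weighted growth model and return point estimates.

    ``panel_or_arrays`` may be a long panel DataFrame or a
    :class:`~panelmsm.engine.PanelArrays`.  ``weights`` is an
    ``[n_persons, n_waves]`` array of final weights (or a tidy frame with
    ``person_id``/``wave``/``w_final``); ``None`` means unit weights.
    """
    if isinstance(panel_or_arrays, PanelArrays):
        arrays = panel_or_arrays
    else:
        arrays = panel_to_arrays(panel_or_arrays)
    if weights is None:
        w_final = np.where(arrays.active, 1.0, np.nan)
    elif isinstance(weights, pd.DataFrame):
        w_final = _weights_frame_to_array(weights, arrays)
    else:
        w_final = weights
    X, y, w, person = growth_rows(arrays, w_final)
    X = _maybe_quadratic(X, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient growth-model design")
    n_persons = int(np.unique(person).size)

    estimator_used = spec.estimator
    converged = True
    if spec.estimator == "weighted_mixed" and spec.random_effects != "none":
        try:
            beta, converged = _fit_weighted_mixed(X, y, w, person, spec)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"weighted_mixed failed ({exc}); falling back to weighted_gls_independence"
            )
            beta = wls_fit(X, y, w)
            estimator_used = "weighted_gls_independence"
            converged = False
    else:
        beta = wls_fit(X, y, w)
        if spec.estimator == "weighted_mixed":
            estimator_used = "weighted_gls_independence"
    return MSMResult(
        beta_intercept=float(beta[0]),
        beta_exposure=float(beta[1]),
        beta_time=float(beta[2]),
        beta_interaction=float(beta[3]),
        beta_quadratic=float(beta[4]) if spec.include_quadratic_time else None,
        estimator_used=estimator_used,
        n_obs=int(y.size),
        n_persons=n_persons,
        converged=converged,
    )


def _weights_frame_to_array(weights: pd.DataFrame, arrays: PanelArrays) -> np.ndarray:
    out = np.full((arrays.n, arrays.n_waves), np.nan)
    pos = {pid: i for i, pid in enumerate(arrays.ids)}
    rows = weights[schema.ID].map(pos).to_numpy()
    out[rows, weights[schema.WAVE].to_numpy(dtype=int)] = weights["w_final"].to_numpy(dtype=float)
    return out


def fit_naive_adjusted(panel: pd.DataFrame) -> MSMResult:
    """Unweighted comparator: OLS of the outcome on exposure, time, their
    interaction, baseline covariates and the *current* time-varying
    confounders — the standard covariate-adjustment approach that is biased
    under exposure-confounder feedback."""
    arrays = panel_to_arrays(panel)
    mask = arrays.active & np.isfinite(arrays.Y) & np.isfinite(arrays.A)
    mask &= np.isfinite(arrays.L).all(axis=2)
    person, wave = np.nonzero(mask)
    t = arrays.time[wave]
    a = arrays.A[person, wave]
    X = np.column_stack(
        [np.ones(person.size), a, t, a * t, arrays.V[person], arrays.L[person, wave, :]]
    )
    y = arrays.Y[person, wave]
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return MSMResult(
        beta_intercept=float(beta[0]),
        beta_exposure=float(beta[1]),
        beta_time=float(beta[2]),
        beta_interaction=float(beta[3]),
        estimator_used="naive_adjusted_ols",
        n_obs=int(y.size),
        n_persons=int(np.unique(person).size),
    )


def excess_aging_per_decade(beta_interaction: float, beta_time: float) -> float:
    """Excess years of outcome aging per 10-year period.

    Divides the exposed-vs-unexposed difference in yearly rates of decline
    by the yearly rate of decline of the unexposed and multiplies by 10.
    Positive values mean the exposed age faster.  Scale-invariant.
    """
    if beta_time == 0:
        raise ZeroDivisionError("excess aging is undefined when the time coefficient is 0")
    return (beta_interaction / beta_time) * 10.0


def predict_regime_trajectories(result: MSMResult, horizon_years: float) -> pd.DataFrame:
    """Predicted mean outcome under always- vs never-exposed regimes."""
    t = np.arange(0.0, horizon_years + 1e-9, schema.YEARS_PER_WAVE)
    never = result.beta_intercept + result.beta_time * t
    always = (
        result.beta_intercept
        + result.beta_exposure
        + (result.beta_time + result.beta_interaction) * t
    )
    return pd.DataFrame({"time_years": t, "never_exposed": never, "always_exposed": always})
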