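"""Synthetic longitudinal cohort generator with known causal truth.

The generator realizes the full time-varying confounding structure of the
target design: time-varying covariates ``L`` are influenced by prior
exposure (feedback) and influence future exposure (confounding); a
person-level frailty ties the covariates that drive censoring to the
outcome trajectory so that censoring weighting has real work to do; death
is a competing terminal event.

Within a wave the ordering is: death -> censoring -> covariates L_t ->
exposure A_t -> outcome Y_t.  Exposure at wave ``t >= 1`` depends on
``(A_{t-1}, L_{t-1}, V)`` — the covariates most recently measured before
the exposure report — so the per-wave propensity model conditioning on
lag-1 covariates is correctly specified by construction.

The exposure acts on the outcome through the slope, ``psi * A_t * t``, so
the true always-exposed vs never-exposed slope difference equals
``slope_effect_psi`` up to a small covariate-mediated component (kept
small by the default outcome loadings; see ``evaluate_true_regime_difference``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import schema
from .schema import ACTIVE, DEAD, LOST, YEARS_PER_WAVE

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_cohort",
    "simulate_panel",
    "evaluate_true_regime_difference",
    "inject_item_missingness",
]

# order of the model time-varying covariates throughout this module
_L_NAMES = ("married", "log_eq_income", "chronic_count", "depressive_sx")

# internal standardization constants for L in the exposure/censoring logits
_L_CENTER = np.array([0.55, 10.0, 1.8, 1.8])
_L_SCALE = np.array([0.50, 1.0, 1.5, 1.5])

# baseline-covariate coefficients in the exposure model (scaled by v_strength);
# order: age_z, sex, education_z, race_group, parental_edu_gt_hs, born_south
_V_EXPOSURE_COEFS = np.array([-0.15, 0.10, -0.30, -0.30, -0.15, 0.15])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults give a cohort shaped like the target study."""

    n_subjects: int = 5000
    n_waves: int = 10
    baseline_age_mean: float = 67.7
    baseline_age_sd: float = 10.95
    exposure_baseline_logit: float = -2.75
    exposure_persistence: float = 2.2
    #: coefficients of standardized (married, log income, chronic, depressive)
    #: in the exposure model
    confounding_strength: tuple[float, float, float, float] = (-0.25, -0.50, 0.30, 0.0)
    #: additional outcome slope per SD of education (cognitive-reserve analogue)
    education_slope_per_sd: float = 0.004
    #: multiplier on the baseline-covariate coefficients of the exposure model
    v_strength: float = 1.0
    #: multiplier on the exposure -> future-covariate (feedback) effects
    feedback_strength: float = 1.0
    frailty_sd: float = 1.0
    frailty_slope_coef: float = -0.008
    #: frailty loadings of (log income, chronic count, depressive symptoms)
    frailty_loadings: tuple[float, float, float] = (-0.05, 0.10, 0.80)
    outcome_intercept_mean: float = 0.9
    outcome_intercept_sd: float = 0.45
    slope_mean: float = -0.045
    slope_effect_psi: float = -0.003
    random_slope_sd: float = 0.01
    residual_sd: float = 0.30
    #: outcome loadings on (married, log income, chronic, depressive)
    outcome_l_coeffs: tuple[float, float, float, float] = (0.006, 0.006, -0.003, -0.002)
    #: censoring hazard: intercept, A_{t-1}, z(income)_{t-1}, z(depressive)_{t-1}, age_z
    censoring_logit_coeffs: tuple[float, ...] = (-3.2, 0.30, -0.30, 0.40, 0.20)
    #: death hazard: intercept, A_{t-1}, age_z, sex, smokes_{t-1}
    death_logit_coeffs: tuple[float, ...] = (-3.3, 0.25, 0.90, -0.30, 0.40)
    item_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_waves < 2:
            raise ValueError(f"n_waves must be >= 2, got {self.n_waves}")
        for name in (
            "baseline_age_sd",
            "frailty_sd",
            "outcome_intercept_sd",
            "random_slope_sd",
            "residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.item_missing_rate <= 1.0:
            raise ValueError(
                f"item_missing_rate must be in [0, 1], got {self.item_missing_rate}"
            )
        if len(self.confounding_strength) != 4:
            raise ValueError("confounding_strength must have 4 entries")
        if len(self.outcome_l_coeffs) != 4:
            raise ValueError("outcome_l_coeffs must have 4 entries")

    def without_confounding(self) -> "SimParams":
        """Copy with exposure-covariate confounding, feedback, censoring and
        death dependence switched off (the no-confounding limit)."""
        return replace(
            self,
            confounding_strength=(0.0, 0.0, 0.0, 0.0),
            v_strength=0.0,
            feedback_strength=0.0,
            censoring_logit_coeffs=(self.censoring_logit_coeffs[0], 0, 0, 0, 0),
            death_logit_coeffs=(self.death_logit_coeffs[0], 0, 0, 0, 0),
        )


@dataclass(frozen=True)
class SimTruth:
    """Monte-Carlo ground truth for the always- vs never-exposed slope contrast."""

    params: SimParams
    true_slope_difference: float
    mc_se: float


_SUBSTREAMS = (
    "baseline",
    "covariates",
    "exposure",
    "outcome",
    "censoring",
    "death",
    "missingness",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.Generator(np.random.PCG64(c)) for name, c in zip(_SUBSTREAMS, children)}


def _draw_baseline(params: SimParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = params.n_subjects
    age0 = np.clip(rng.normal(params.baseline_age_mean, params.baseline_age_sd, n), 50.0, 100.0)
    sex = (rng.random(n) < 0.60).astype(float)  # 1 = female
    education = np.clip(rng.normal(13.0, 3.0, n), 0.0, 20.0)
    childhood_ses = rng.normal(0.0, 1.0, n)
    parental = (rng.random(n) < _sigmoid(-0.7 + 1.2 * childhood_ses)).astype(float)
    born_south = (rng.random(n) < _sigmoid(-0.8 - 0.5 * childhood_ses)).astype(float)
    race = (rng.random(n) < 0.80).astype(float)  # 1 = reference group
    frailty = rng.normal(0.0, params.frailty_sd, n)
    return {
        "age0": age0,
        "sex": sex,
        "education_years": education,
        "race_group": race,
        "parental_edu_gt_hs": parental,
        "born_south": born_south,
        "childhood_ses": childhood_ses,
        "frailty": frailty,
    }


def _v_matrix(base: dict[str, np.ndarray]) -> np.ndarray:
    """Standardized V design used inside the exposure logit."""
    return np.column_stack(
        [
            (base["age0"] - 67.7) / 11.0,
            base["sex"],
            (base["education_years"] - 13.0) / 3.0,
            base["race_group"],
            base["parental_edu_gt_hs"],
            base["born_south"],
        ]
    )


class _CovariateState:
    """Vectorized state machine for the time-varying covariates."""

    def __init__(self, params: SimParams, base: dict[str, np.ndarray], rng: np.random.Generator):
        self.params = params
        self.rng = rng
        n = params.n_subjects
        u = base["frailty"]
        edu = base["education_years"]
        self.u = u
        self.age_z = (base["age0"] - 67.7) / 11.0
        lu_inc, lu_chr, lu_dep = params.frailty_loadings
        self.income_mu = 10.0 + lu_inc * u + 0.08 * (edu - 13.0)
        self.income = self.income_mu + rng.normal(0.0, 0.6, n)
        self.dep_latent = lu_dep * u + rng.normal(0.0, 0.9, n)
        self.married = (rng.random(n) < _sigmoid(0.25 - 0.1 * u)).astype(float)
        self.chronic = rng.binomial(2, _sigmoid(-1.2 + lu_chr * u + 0.35 * self.age_z)).astype(float)
        self.wealth_mu = 11.0 - 0.5 * u + 0.10 * (edu - 13.0)
        self.wealth = self.wealth_mu + rng.normal(0.0, 1.2, n)
        self.bmi = 27.0 + 0.3 * u + rng.normal(0.0, 4.0, n)
        self.drinks = (rng.random(n) < 0.45).astype(float)
        self.smokes = (rng.random(n) < 0.15).astype(float)

    @property
    def dep(self) -> np.ndarray:
        return np.clip(np.round(1.8 + self.dep_latent), 0.0, 8.0)

    def model_l(self) -> np.ndarray:
        """Current (married, log income, chronic, depressive) as columns."""
        return np.column_stack([self.married, self.income, self.chronic, self.dep])

    def step(self, a_prev: np.ndarray) -> None:
        """Advance one wave given previous exposure (vector of 0/1)."""
        p, rng = self.params, self.rng
        n = p.n_subjects
        fb = p.feedback_strength
        self.income = (
            self.income_mu
            + 0.6 * (self.income - self.income_mu)
            + fb * (-0.05) * a_prev
            + rng.normal(0.0, 0.5, n)
        )
        lu_dep = p.frailty_loadings[2]
        self.dep_latent = (
            0.5 * self.dep_latent + 0.5 * lu_dep * self.u + fb * 0.15 * a_prev
            + rng.normal(0.0, 0.7, n)
        )
        p_new = _sigmoid(-2.3 + p.frailty_loadings[1] * self.u + 0.35 * self.age_z + fb * 0.15 * a_prev)
        self.chronic = np.minimum(8.0, self.chronic + (rng.random(n) < p_new))
        stay = _sigmoid(3.35 - fb * 0.6 * a_prev)  # ~0.966 if unexposed
        form = 0.02
        m_draw = rng.random(n)
        self.married = np.where(
            self.married == 1.0, (m_draw < stay).astype(float), (m_draw < form).astype(float)
        )
        self.wealth = (
            self.wealth_mu
            + 0.8 * (self.wealth - self.wealth_mu)
            + fb * (-0.08) * a_prev
            + rng.normal(0.0, 0.7, n)
        )
        self.bmi = self.bmi + rng.normal(0.0, 0.8, n)
        d_draw = rng.random(n)
        self.drinks = np.where(self.drinks == 1.0, (d_draw < 0.90).astype(float), (d_draw < 0.10).astype(float))
        self.smokes = self.smokes * (rng.random(n) >= 0.05)

    def full_row(self) -> dict[str, np.ndarray]:
        return {
            "married": self.married.copy(),
            "log_eq_income": self.income.copy(),
            "log_eq_wealth": self.wealth.copy(),
            "chronic_count": self.chronic.copy(),
            "depressive_sx": self.dep.copy(),
            "bmi": self.bmi.copy(),
            "drinks": self.drinks.copy(),
            "smokes": self.smokes.copy(),
        }


def _exposure_logit(
    params: SimParams, l_mat: np.ndarray, v_mat: np.ndarray, a_prev: np.ndarray | None
) -> np.ndarray:
    z = (l_mat - _L_CENTER) / _L_SCALE
    # baseline-covariate selection acts mostly at cohort entry; transitions
    # retain half of it (exposure persistence carries the rest forward)
    v_scale = 1.0 if a_prev is None else 0.5
    logit = (
        params.exposure_baseline_logit
        + z @ np.asarray(params.confounding_strength)
        + params.v_strength * v_scale * (v_mat @ _V_EXPOSURE_COEFS)
    )
    if a_prev is not None:
        logit = logit + params.exposure_persistence * a_prev
    return logit


def _simulate_arrays(
    params: SimParams,
    rngs: dict[str, np.random.Generator],
    *,
    fixed_exposure: float | None = None,
    attrition: bool = True,
    base: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Run the generator, returning wide [n_subjects, n_waves] arrays.

    ``fixed_exposure`` forces a static regime (used by the truth oracle);
    ``attrition=False`` switches censoring and death off.  ``base`` lets the
    oracle reuse identical baseline draws across regimes.
    """
    n, t_max = params.n_subjects, params.n_waves
    if base is None:
        base = _draw_baseline(params, rngs["baseline"])
    v_mat = _v_matrix(base)
    state = _CovariateState(params, base, rngs["covariates"])

    intercept = (
        rngs["outcome"].normal(params.outcome_intercept_mean, params.outcome_intercept_sd, n)
        - 0.25 * base["frailty"]
        + 0.03 * (base["education_years"] - 13.0)
    )
    slope = (
        params.slope_mean
        + params.random_slope_sd * rngs["outcome"].standard_normal(n)
        + params.frailty_slope_coef * base["frailty"]
        + params.education_slope_per_sd * (base["education_years"] - 13.0) / 3.0
    )
    noise = rngs["outcome"].normal(0.0, params.residual_sd, (n, t_max))

    A = np.full((n, t_max), np.nan)
    Y = np.full((n, t_max), np.nan)
    L_full = {name: np.full((n, t_max), np.nan) for name in schema.TIMEVARYING_COVARIATES}
    status = np.full((n, t_max), ACTIVE, dtype=object)
    alive_obs = np.ones(n, dtype=bool)  # active (alive and under observation)
    ever_dead = np.zeros(n, dtype=bool)
    ever_lost = np.zeros(n, dtype=bool)

    cens = np.asarray(params.censoring_logit_coeffs)
    death = np.asarray(params.death_logit_coeffs)

    l_prev = state.model_l()
    for t in range(t_max):
        if t > 0:
            a_prev = A[:, t - 1]
            a_prev_f = np.where(np.isnan(a_prev), 0.0, a_prev)
            if attrition:
                z_prev = (l_prev - _L_CENTER) / _L_SCALE
                d_logit = (
                    death[0]
                    + death[1] * a_prev_f
                    + death[2] * state.age_z
                    + death[3] * base["sex"]
                    + death[4] * state.smokes
                )
                dies = alive_obs & (rngs["death"].random(n) < _sigmoid(d_logit))
                c_logit = (
                    cens[0]
                    + cens[1] * a_prev_f
                    + cens[2] * z_prev[:, 1]
                    + cens[3] * z_prev[:, 3]
                    + cens[4] * state.age_z
                )
                lost = alive_obs & ~dies & (rngs["censoring"].random(n) < _sigmoid(c_logit))
                newly_dead = dies & ~ever_dead & ~ever_lost
                newly_lost = lost & ~ever_dead & ~ever_lost
                status[newly_dead, t] = DEAD
                status[newly_lost, t] = LOST
                ever_dead |= newly_dead
                ever_lost |= newly_lost
                alive_obs &= ~(newly_dead | newly_lost)
            state.step(a_prev_f)

        l_now = state.model_l()
        if fixed_exposure is not None:
            a_t = np.full(n, float(fixed_exposure))
        else:
            if t == 0:
                logit = _exposure_logit(params, l_now, v_mat, None)
            else:
                logit = _exposure_logit(params, l_prev, v_mat, A[:, t - 1])
            a_t = (rngs["exposure"].random(n) < _sigmoid(logit)).astype(float)

        time_years = YEARS_PER_WAVE * t
        y_t = (
            intercept
            + (slope + params.slope_effect_psi * a_t) * time_years
            + l_now @ np.asarray(params.outcome_l_coeffs)
            + noise[:, t]
        )

        A[alive_obs, t] = a_t[alive_obs]
        Y[alive_obs, t] = y_t[alive_obs]
        row = state.full_row()
        for name in schema.TIMEVARYING_COVARIATES:
            L_full[name][alive_obs, t] = row[name][alive_obs]
        l_prev = l_now

    return {"A": A, "Y": Y, "L": L_full, "status": status, "base": base}


def _arrays_to_panel(params: SimParams, arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    n, t_max = params.n_subjects, params.n_waves
    status = arrays["status"]
    # keep rows up to and including the terminal (lost/dead) wave
    terminal = status != ACTIVE
    first_term = np.where(terminal.any(axis=1), terminal.argmax(axis=1), t_max - 1)
    keep = np.arange(t_max)[None, :] <= first_term[:, None]

    pid = np.repeat(np.arange(n), t_max)[keep.ravel()]
    wave = np.tile(np.arange(t_max), n)[keep.ravel()]
    data = {
        schema.ID: pid,
        schema.WAVE: wave,
        schema.TIME: wave * YEARS_PER_WAVE,
        schema.STATUS: status.ravel()[keep.ravel()],
        schema.RESPONDED: (status.ravel()[keep.ravel()] == ACTIVE).astype(int),
        schema.EXPOSURE: arrays["A"].ravel()[keep.ravel()],
        schema.OUTCOME: arrays["Y"].ravel()[keep.ravel()],
    }
    base = arrays["base"]
    for name in schema.BASELINE_COVARIATES:
        data[name] = np.repeat(base[name], t_max)[keep.ravel()]
    data[schema.CHILDHOOD_SES] = np.repeat(base["childhood_ses"], t_max)[keep.ravel()]
    for name in schema.TIMEVARYING_COVARIATES:
        data[name] = arrays["L"][name].ravel()[keep.ravel()]
    return pd.DataFrame(data)


def simulate_panel(params: SimParams) -> pd.DataFrame:
    """Generate just the observational panel (no truth evaluation)."""
    rngs = _rngs(params.seed)
    arrays = _simulate_arrays(params, rngs)
    panel = _arrays_to_panel(params, arrays)
    if params.item_missing_rate > 0:
        panel = _inject_missing(panel, params.item_missing_rate, rngs["missingness"])
    return panel


def simulate_cohort(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Generate an observational cohort and its Monte-Carlo ground truth.

    Returns the long-format panel and a :class:`SimTruth` whose
    ``true_slope_difference`` is evaluated by
    :func:`evaluate_true_regime_difference` at a default precision.
    Deterministic given ``params.seed``.
    """
    panel = simulate_panel(params)
    truth = evaluate_true_regime_difference(params, n_mc=20_000)
    return panel, truth


def evaluate_true_regime_difference(params: SimParams, n_mc: int = 20_000) -> SimTruth:
    """Monte-Carlo oracle for the always- vs never-exposed slope contrast.

    Simulates counterfactual outcome trajectories under the two static
    regimes with shared random draws and censoring/death disabled, fits the
    per-person OLS slope under each regime, and returns the mean paired
    difference with its Monte-Carlo standard error.
    """
    if n_mc < 1000:
        raise ValueError(f"n_mc must be >= 1000, got {n_mc}")
    mc_params = replace(params, n_subjects=int(n_mc))
    # identical substreams for both regimes -> paired comparison
    base = _draw_baseline(mc_params, _rngs(mc_params.seed)["baseline"])
    y_by_regime = {}
    for regime in (1.0, 0.0):
        rngs = _rngs(mc_params.seed)
        arrays = _simulate_arrays(
            mc_params, rngs, fixed_exposure=regime, attrition=False, base=base
        )
        y_by_regime[regime] = arrays["Y"]
    t = YEARS_PER_WAVE * np.arange(mc_params.n_waves)
    tc = t - t.mean()
    denom = (tc**2).sum()
    slope1 = (y_by_regime[1.0] * tc).sum(axis=1) / denom
    slope0 = (y_by_regime[0.0] * tc).sum(axis=1) / denom
    diff = slope1 - slope0
    mc_se = max(float(diff.std(ddof=1) / np.sqrt(n_mc)), 1e-12)
    return SimTruth(params=params, true_slope_difference=float(diff.mean()), mc_se=mc_se)


_MISSABLE = [schema.EXPOSURE] + schema.TIMEVARYING_COVARIATES


def _inject_missing(panel: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    panel = panel.copy()
    eligible = (
        (panel[schema.STATUS] == ACTIVE)
        & (panel[schema.RESPONDED] == 1)
        & (panel[schema.WAVE] > 0)
    ).to_numpy()
    for col in _MISSABLE:
        blank = eligible & (rng.random(len(panel)) < rate)
        panel.loc[blank, col] = np.nan
    return panel


def inject_item_missingness(panel: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank exposure and time-varying covariates independently at ``rate``
    among active, responded post-baseline person-waves.  Wave-0 exposure is
    never blanked (baseline completeness is an eligibility criterion)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    return _inject_missing(panel, rate, rng)
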