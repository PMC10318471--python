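"""Descriptive tables, result tables and diagnostic figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from .growth import MSMResult, predict_regime_trajectories
from .weights import BalanceReport, FinalWeights

__all__ = [
    "describe_baseline",
    "attrition_table",
    "results_table",
    "plot_balance",
    "plot_trajectories",
    "plot_weight_distribution",
]

#: skewed variables summarized as median (IQR) rather than mean (SD)
_SKEWED = ["log_eq_income", "log_eq_wealth", "chronic_count", "depressive_sx"]
_BINARY = [
    "sex",
    "race_group",
    "parental_edu_gt_hs",
    "born_south",
    "married",
    "drinks",
    "smokes",
]
_CONTINUOUS = ["age0", "education_years", "bmi", "outcome"]


def _summarize(series: pd.Series, kind: str) -> str:
    s = series.dropna()
    if len(s) == 0:
        return ""
    if kind == "binary":
        return f"{int(s.sum())} ({100.0 * s.mean():.1f}%)"
    if kind == "skewed":
        q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
        return f"{med:.2f} ({q1:.2f}-{q3:.2f})"
    return f"{s.mean():.2f} ({s.std():.2f})"


def baseline_prevalence_percent(panel: pd.DataFrame, decimals: int = 1) -> float:
    """Percentage exposed at wave 0 among persons with observed baseline exposure."""
    w0 = panel.loc[panel[schema.WAVE] == 0, schema.EXPOSURE].dropna()
    if len(w0) == 0:
        raise ValueError("no baseline exposure data")
    return round(100.0 * float(w0.mean()), decimals)


def describe_baseline(panel: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics, overall and stratified by baseline exposure.

    Continuous variables as mean (SD), binary as n (%), skewed (income,
    wealth, condition and symptom counts) as median (IQR).
    """
    w0 = panel.loc[panel[schema.WAVE] == 0].copy()
    strata = {"overall": w0}
    if w0[schema.EXPOSURE].notna().any():
        strata["unexposed"] = w0.loc[w0[schema.EXPOSURE] == 0]
        strata["exposed"] = w0.loc[w0[schema.EXPOSURE] == 1]
    rows = [
        {"variable": "n", **{name: str(len(df)) for name, df in strata.items()}},
    ]
    variables = [(v, "continuous") for v in _CONTINUOUS if v in w0.columns]
    variables += [(v, "binary") for v in _BINARY if v in w0.columns]
    variables += [(v, "skewed") for v in _SKEWED if v in w0.columns]
    for var, kind in variables:
        rows.append(
            {"variable": var, **{name: _summarize(df[var], kind) for name, df in strata.items()}}
        )
    return pd.DataFrame(rows)


def attrition_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Final-status counts (active / lost / dead), overall and by baseline exposure."""
    last = panel.sort_values([schema.ID, schema.WAVE]).groupby(schema.ID).tail(1)
    base_exp = (
        panel.loc[panel[schema.WAVE] == 0].set_index(schema.ID)[schema.EXPOSURE]
    )
    last = last.assign(baseline_exposure=last[schema.ID].map(base_exp))
    overall = last[schema.STATUS].value_counts().rename("overall")
    by_exp = last.pivot_table(
        index=schema.STATUS, columns="baseline_exposure", values=schema.ID, aggfunc="count"
    )
    out = pd.concat([overall, by_exp], axis=1).fillna(0).astype(int)
    out.columns = ["overall"] + [f"baseline_exposure_{int(c)}" for c in by_exp.columns]
    return out.reset_index(names="final_status")


def results_table(results: list[MSMResult]) -> pd.DataFrame:
    """Coefficient / 95% CI / excess-years table, one block per result."""
    rows = []
    for r in results:
        label = r.scenario or "base"
        for coef, value in (
            ("exposure", r.beta_exposure),
            ("time", r.beta_time),
            ("interaction", r.beta_interaction),
        ):
            ci = r.ci.get(coef) if r.ci else None
            rows.append(
                {
                    "model": label,
                    "coefficient": coef,
                    "estimate": value,
                    "ci_lower": ci[0] if ci else np.nan,
                    "ci_upper": ci[1] if ci else np.nan,
                    "excess_years_per_decade": (
                        r.excess_years_per_decade if coef == "interaction" else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def plot_balance(reports: list[BalanceReport], path):
    """Love-style plot of SMDs before/after weighting across waves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for rep in reports:
        if rep.smd.empty:
            continue
        ax.scatter(
            [rep.wave] * len(rep.smd), rep.smd["smd_unweighted"].abs(), c="tab:red", s=12,
            label="unweighted" if rep.wave == reports[0].wave else None,
        )
        ax.scatter(
            [rep.wave] * len(rep.smd), rep.smd["smd_weighted"].abs(), c="tab:blue", s=12,
            label="weighted" if rep.wave == reports[0].wave else None,
        )
    ax.axhline(0.25, ls="--", c="gray")
    ax.set_xlabel("wave")
    ax.set_ylabel("|standardized mean difference|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(result: MSMResult, horizon_years: float, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = predict_regime_trajectories(result, horizon_years)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj["time_years"], traj["never_exposed"], label="never exposed")
    ax.plot(traj["time_years"], traj["always_exposed"], label="always exposed", ls="--")
    ax.set_xlabel("years since baseline")
    ax.set_ylabel("outcome (SD units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return traj


def plot_weight_distribution(weights: FinalWeights, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(weights.table["w_final"], bins=60)
    for b in weights.truncation_bounds:
        ax.axvline(b, c="tab:red", ls="--")
    ax.set_xlabel("final weight")
    ax.set_ylabel("person-waves")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
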