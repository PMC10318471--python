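import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelmsm import schema
from panelmsm.schema import validate_panel
from panelmsm.simulate import (
    SimParams,
    evaluate_true_regime_difference,
    inject_item_missingness,
    simulate_cohort,
    simulate_panel,
)


class TestSimParams:
    def test_defaults_valid(self):
        SimParams()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_subjects", 0),
            ("n_waves", 1),
            ("residual_sd", -0.1),
            ("random_slope_sd", -1.0),
            ("item_missing_rate", 1.5),
        ],
    )
    def test_invalid_rejected_with_name(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimParams(**{field: value})


class TestSimulatePanel:
    def test_same_seed_identical(self):
        a = simulate_panel(SimParams(n_subjects=300, seed=5))
        b = simulate_panel(SimParams(n_subjects=300, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_panel(SimParams(n_subjects=300, seed=5))
        b = simulate_panel(SimParams(n_subjects=300, seed=6))
        assert not a.equals(b)

    def test_schema_valid(self, default_cohort):
        _, panel, _ = default_cohort
        validate_panel(panel)

    def test_status_monotone(self, default_cohort):
        _, panel, _ = default_cohort
        df = panel.sort_values([schema.ID, schema.WAVE])
        terminal = df[schema.STATUS].isin([schema.LOST, schema.DEAD]).to_numpy()
        same = df[schema.ID].to_numpy()[1:] == df[schema.ID].to_numpy()[:-1]
        assert not np.any(terminal[:-1] & same)

    def test_no_values_after_death(self, default_cohort):
        _, panel, _ = default_cohort
        dead = panel.loc[panel[schema.STATUS] == schema.DEAD]
        cols = [schema.EXPOSURE, schema.OUTCOME] + schema.TIMEVARYING_COVARIATES
        assert dead[cols].isna().all().all()

    def test_baseline_prevalence_near_target(self, default_cohort):
        _, panel, _ = default_cohort
        prev = panel.loc[panel[schema.WAVE] == 0, schema.EXPOSURE].mean()
        assert 0.03 < prev < 0.07

    def test_baseline_age_at_least_50(self, default_cohort):
        _, panel, _ = default_cohort
        assert (panel["age0"] >= 50).all()

    def test_wave_prevalence_matches_generative_model(self):
        # empirical prevalence vs the generative model's implied marginal
        # prevalence, obtained by averaging the exposure logit over the
        # realized covariate histories (Rao-Blackwellized oracle)
        from scipy.special import expit

        from panelmsm.simulate import _L_NAMES, _exposure_logit, _v_matrix

        params = SimParams(n_subjects=50_000, seed=11)
        panel = simulate_panel(params)
        w0 = panel.loc[panel[schema.WAVE] == 0]
        base = {c: w0[c].to_numpy() for c in schema.BASELINE_COVARIATES}
        v_mat = _v_matrix(base)
        l0 = w0[list(_L_NAMES)].to_numpy()
        p_implied = expit(_exposure_logit(params, l0, v_mat, None)).mean()
        p_emp = w0[schema.EXPOSURE].mean()
        se = np.sqrt(p_implied * (1 - p_implied) / len(w0))
        assert abs(p_emp - p_implied) < 4 * se


class TestNoConfoundingLimit:
    def test_naive_and_weighted_agree(self):
        from panelmsm.growth import fit_naive_adjusted
        from panelmsm.pipeline import analyze_panel
        from panelmsm.prep import prepare_panel

        from conftest import GLS_CONFIG

        params = SimParams(n_subjects=20_000, seed=21).without_confounding()
        panel = simulate_panel(params)
        prepped, _ = prepare_panel(panel)
        wtd = analyze_panel(prepped, GLS_CONFIG).result.beta_interaction
        naive = fit_naive_adjusted(prepped).beta_interaction
        assert abs(wtd - naive) < 0.002

    def test_observational_contrast_matches_psi(self):
        # with confounding disabled the unadjusted pooled interaction
        # coefficient is within sampling error of psi
        params = SimParams(n_subjects=40_000, seed=22).without_confounding()
        panel = simulate_panel(params)
        sub = panel[panel[schema.OUTCOME].notna() & panel[schema.EXPOSURE].notna()]
        a = sub[schema.EXPOSURE].to_numpy()
        t = sub[schema.TIME].to_numpy()
        y = sub[schema.OUTCOME].to_numpy()
        X = np.column_stack([np.ones_like(t), a, t, a * t])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[3] == pytest.approx(-0.003, abs=0.002)


class TestTruthOracle:
    def test_null_effect(self):
        # with feedback off the two regimes share identical covariate paths,
        # so a null psi gives an exactly-null regime difference
        truth = evaluate_true_regime_difference(
            SimParams(slope_effect_psi=0.0, feedback_strength=0.0, seed=3), n_mc=5000
        )
        assert abs(truth.true_slope_difference) <= max(2 * truth.mc_se, 1e-12)

    def test_null_effect_with_feedback_leaves_small_mediated_residue(self):
        truth = evaluate_true_regime_difference(
            SimParams(slope_effect_psi=0.0, seed=3), n_mc=5000
        )
        assert abs(truth.true_slope_difference) < 3e-4

    def test_recovers_psi(self):
        truth = evaluate_true_regime_difference(SimParams(seed=4), n_mc=20_000)
        assert truth.true_slope_difference == pytest.approx(-0.003, abs=3e-4)
        assert truth.mc_se > 0

    def test_mc_se_scaling(self):
        t1 = evaluate_true_regime_difference(SimParams(seed=5), n_mc=4000)
        t2 = evaluate_true_regime_difference(SimParams(seed=5), n_mc=8000)
        assert t2.mc_se == pytest.approx(t1.mc_se / np.sqrt(2), rel=0.25)

    def test_small_n_mc_rejected(self):
        with pytest.raises(ValueError):
            evaluate_true_regime_difference(SimParams(), n_mc=10)

    @pytest.mark.parametrize("seed", range(5))
    def test_regime_oracle_consistency_across_seeds(self, seed):
        truth = evaluate_true_regime_difference(SimParams(seed=seed), n_mc=5000)
        # additive-on-slope generator: truth ~= psi (small mediated residue)
        assert truth.true_slope_difference == pytest.approx(-0.003, abs=6e-4)


class TestItemMissingness:
    def test_rate_zero_unchanged(self, default_cohort):
        _, panel, _ = default_cohort
        out = inject_item_missingness(panel, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, panel)

    def test_rate_one_blanks_all_postbaseline(self, default_cohort):
        _, panel, _ = default_cohort
        out = inject_item_missingness(panel, 1.0, seed=1)
        post = out.loc[
            (out[schema.WAVE] > 0) & (out[schema.STATUS] == schema.ACTIVE),
            schema.EXPOSURE,
        ]
        assert post.isna().all()

    def test_wave0_exposure_never_blanked(self, default_cohort):
        _, panel, _ = default_cohort
        out = inject_item_missingness(panel, 1.0, seed=1)
        assert out.loc[out[schema.WAVE] == 0, schema.EXPOSURE].notna().all()

    def test_empirical_rate(self, default_cohort):
        _, panel, _ = default_cohort
        out = inject_item_missingness(panel, 0.1, seed=2)
        post = (out[schema.WAVE] > 0) & (out[schema.STATUS] == schema.ACTIVE)
        frac = out.loc[post, schema.EXPOSURE].isna().mean()
        n = int(post.sum())
        assert abs(frac - 0.1) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_bad_rate_rejected(self, default_cohort):
        _, panel, _ = default_cohort
        with pytest.raises(ValueError):
            inject_item_missingness(panel, -0.2, seed=0)

    @given(rate=st.floats(0.0, 1.0), seed=st.integers(0, 10))
    @settings(max_examples=10, deadline=None)
    def test_outcomes_never_blanked(self, rate, seed):
        panel = simulate_panel(SimParams(n_subjects=100, seed=1))
        out = inject_item_missingness(panel, rate, seed=seed)
        pd.testing.assert_series_equal(out[schema.OUTCOME], panel[schema.OUTCOME])
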