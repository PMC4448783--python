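import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import thermperf as tp


class TestStandardize:
    def test_symmetric_triple(self):
        t = pd.DataFrame({"ucrit_bl_s": [1.0, 2.0, 3.0]})
        out = tp.standardize_response(t)
        assert np.allclose(out["ucrit_z"], [-1.0, 0.0, 1.0])

    def test_constant_input_rejected(self):
        t = pd.DataFrame({"ucrit_bl_s": [2.0, 2.0, 2.0]})
        with pytest.raises(tp.DesignError):
            tp.standardize_response(t)

    @given(st.lists(st.floats(0.5, 30.0), min_size=3, max_size=40,
                    unique=True))
    def test_mean_zero_sd_one(self, values):
        out = tp.standardize_response(pd.DataFrame({"ucrit_bl_s": values}))
        assert out["ucrit_z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["ucrit_z"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_idempotence(self, default_dataset):
        once = tp.standardize_response(default_dataset)
        twice = tp.standardize_response(once, source="ucrit_z",
                                        target="ucrit_z2")
        assert np.allclose(once["ucrit_z"], twice["ucrit_z2"], atol=1e-12)


class TestBuildDesign:
    def test_centering(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        design = tp.build_design(table, 1)
        tt = design.X[:, 2]
        assert np.allclose(tt, table["test_temp_c"] - 28.0)
        assert np.allclose(design.X[:, 3], tt ** 2)
        assert np.allclose(design.X[:, 0], 1.0)

    def test_random_terms_per_model(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        assert tp.build_design(table, 5).random_terms == ("intercept", "AT")
        assert tp.build_design(table, 8).random_terms == (
            "intercept", "AT", "AT:TT", "AT:TT2")
        for mid in range(1, 9):
            d = tp.build_design(table, mid)
            assert d.Z.shape == (len(table), len(d.random_terms))

    def test_unknown_model_id(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        with pytest.raises(tp.DesignError):
            tp.build_design(table, 9)

    def test_missing_column(self):
        with pytest.raises(tp.DesignError):
            tp.build_design(pd.DataFrame({"fish_id": ["a"]}), 1)


class TestFitLMM:
    def test_noisefree_recovery(self, noisefree_params):
        """With every random source off, the fit returns the generating
        coefficients to numerical tolerance."""
        table = tp.simulate_dataset(noisefree_params)
        design = tp.build_design(table, 1)
        fit = tp.fit_lmm(design, method="ML")
        beta = noisefree_params.beta
        for i, term in enumerate(tp.FIXED_TERMS):
            assert fit.beta_hat[term] == pytest.approx(beta[i], abs=1e-6)

    def test_ml_beats_fixed_only_least_squares(self, small_dataset):
        table = tp.standardize_response(small_dataset)
        design = tp.build_design(table, 1)
        fit = tp.fit_lmm(design, method="ML")
        # Gaussian MLE of the fixed-effects-only model
        X, y = design.X, design.y
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = (resid ** 2).mean()
        ll_ols = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1.0)
        assert fit.loglik >= ll_ols - 1e-8

    def test_aic_identity(self, small_dataset):
        table = tp.standardize_response(small_dataset)
        for method in ("ML", "REML"):
            fit = tp.fit_lmm(tp.build_design(table, 5), method=method)
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.loglik)
            assert fit.n_params == 7 + fit.n_varcomp

    @pytest.mark.parametrize("model_id", [1, 2, 5])
    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_loglik_matches_dense_mvn_oracle(self, small_dataset, model_id,
                                             method):
        """The profiled likelihood of the fitting engine agrees with a
        direct dense multivariate-normal evaluation of the marginal model."""
        table = tp.standardize_response(small_dataset)
        design = tp.build_design(table, model_id)
        fit = tp.fit_lmm(design, method=method)
        oracle = tp.dense_mvn_loglik(design, fit.cov_re, fit.resid_var,
                                     method=method)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_varcomp_psd(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        fit = tp.fit_lmm(tp.build_design(table, 8), method="REML")
        assert np.linalg.eigvalsh(fit.cov_re).min() >= -1e-10
        assert fit.resid_var > 0


class TestLadder:
    def test_self_comparison_is_null(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        fit = tp.fit_lmm(tp.build_design(table, 5), method="REML")
        t = tp.lrt(fit, fit)
        assert t.chi2 == pytest.approx(0.0)
        assert t.p == 1.0

    def test_ladder_report_structure_and_nesting(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        report, fits = tp.run_ladder(table)
        assert list(report["model_id"]) == list(range(1, 9))
        assert (report["error"] == "").all()
        ll = {m: f.loglik for m, f in fits.items()}
        # REML loglik is non-decreasing along every nested chain
        for chain in ((1, 2, 4), (1, 3, 4), (1, 5, 6, 8), (5, 7, 8)):
            for lo, hi in zip(chain, chain[1:]):
                assert ll[hi] >= ll[lo] - 1e-4
        lrts = tp.ladder_lrt_table(fits)
        assert (lrts["chi2"] >= 0).all()
        assert ((lrts["p"] >= 0) & (lrts["p"] <= 1)).all()
        assert len(lrts) == len(tp.LADDER_LRT_PAIRS)

    def test_ml_loglik_monotone_in_nesting(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        fits = {m: tp.fit_lmm(tp.build_design(table, m), method="ML")
                for m in (1, 5, 8)}
        assert fits[5].loglik >= fits[1].loglik - 1e-4
        assert fits[8].loglik >= fits[5].loglik - 1e-4

    def test_at_dominated_data_prefers_acclimation_terms(self):
        """With acclimation-response random effects and no acute-slope
        variation, the acclimation-shift model outranks the acute-slope
        models by AIC in most datasets (3 seeds here)."""
        wins = 0
        for seed in (11, 12, 13):
            params = tp.default_params(seed=seed).replace(
                re_sd_tt_at=0.0, re_sd_tt2_at=0.0)
            table = tp.standardize_response(tp.simulate_dataset(params))
            report, _ = tp.run_ladder(table, model_ids=(1, 2, 3, 4, 5))
            aic = dict(zip(report["model_id"], report["aic"]))
            wins += aic[5] < min(aic[2], aic[3], aic[4])
        assert wins >= 2


class TestFixedEffectTable:
    def test_passthrough_and_t_definition(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        fit = tp.fit_lmm(tp.build_design(table, 1), method="ML")
        report = tp.fixed_effect_table(fit)
        assert list(report["term"]) == list(tp.FIXED_TERMS)
        for row in report.itertuples():
            assert row.estimate == fit.beta_hat[row.term]
            assert row.t == pytest.approx(row.estimate / row.se)
            assert 0.0 <= row.p <= 1.0
        assert (report["df"] == fit.n_obs - 7).all()

    def test_wrong_model_or_method_rejected(self, default_dataset):
        table = tp.standardize_response(default_dataset)
        fit5 = tp.fit_lmm(tp.build_design(table, 5), method="REML")
        with pytest.raises(ValueError):
            tp.fixed_effect_table(fit5)
        fit1_reml = tp.fit_lmm(tp.build_design(table, 1), method="REML")
        with pytest.raises(ValueError):
            tp.fixed_effect_table(fit1_reml)
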