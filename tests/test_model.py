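"""Logistic fitting, VIF, stepwise selection, cutoff, calibration, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgkit.io import records_to_frame
from mcgkit.model import (
    StepwiseConfig,
    StepwiseLogit,
    auc_mann_whitney,
    bootstrap_optimism,
    calibration_curve,
    fit_logistic,
    hosmer_lemeshow,
    vif,
    youden_cutoff,
)
from mcgkit.simulate import CohortSpec, simulate_feature_table


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(np.zeros((100, 0)), y, terms=[])
        assert fit.params["const"] == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_two_by_two_log_odds_ratio(self):
        a, b, c, d = 20, 10, 5, 25  # exposed cases, exposed controls, ...
        x = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        fit = fit_logistic(x, y)
        assert fit.params.iloc[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-7)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(8)
        n = 5000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -1.0, 0.3, 0.8])
        eta = beta[0] + X @ beta[1:]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(X, y.astype(int))
        for est, truth, se in zip(fit.params, beta, fit.bse):
            assert abs(est - truth) < 3 * se

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.4).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-5)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_separation_flagged(self):
        x = np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            fit_logistic(x, y)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_logistic(np.zeros((5, 1)), np.ones(5))


class TestVIF:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10000, 4)), columns=list("abcd"))
        v = vif(df, list("abcd"))
        assert ((v >= 1.0) & (v <= 1.1)).all()

    def test_pair_matches_correlation_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=3000)
        y = x + rng.normal(0, 0.1 * x.std(), size=3000)
        df = pd.DataFrame({"x": x, "y": y})
        rho = df.x.corr(df.y)
        v = vif(df, ["x", "y"])
        assert v["x"] == pytest.approx(1 / (1 - rho**2), rel=1e-6)

    def test_exact_collinearity_reports_inf(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6], "y": [2.0, 4, 6, 8, 10, 12]})
        assert np.isinf(vif(df, ["x", "y"])).all()


class TestYouden:
    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_brute_force_scan(self, data):
        n = data.draw(st.integers(min_value=4, max_value=50))
        scores = np.array(data.draw(st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        cut, j = youden_cutoff(scores, labels)
        # independent exhaustive oracle
        best_j, best_cut = -np.inf, None
        for c in sorted(set(scores)):
            se = np.mean(scores[labels == 1] >= c)
            sp = np.mean(scores[labels == 0] < c)
            jj = se + sp - 1
            if jj > best_j + 1e-12:
                best_j, best_cut = jj, c
        assert j == pytest.approx(best_j)
        assert cut == best_cut

    def test_perfect_separation(self):
        cut, j = youden_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert j == 1.0 and 0.2 < cut <= 0.8

    def test_identical_distributions_near_zero_j(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        _, j = youden_cutoff(scores, labels)
        assert j < 0.1


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(4)
        probs = rng.uniform(0.05, 0.95, 500)
        labels = (rng.random(500) < probs).astype(int)
        chi2, df, p, g = hosmer_lemeshow(probs, labels, g=10)
        assert df == 8 and g == 10

    def test_two_group_hand_example(self):
        # group A: probs 0.2 (n=4, 1 event); group B: probs 0.8 (n=4, 3 events)
        probs = np.array([0.2] * 4 + [0.8] * 4)
        labels = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        chi2, df, p, g = hosmer_lemeshow(probs, labels, g=2)
        # manual: each group O=E -> contribution ((1-0.8)^2)/(0.8*0.8) etc.
        expected = (1 - 4 * 0.2) ** 2 / (4 * 0.2 * 0.8) + (3 - 4 * 0.8) ** 2 / (4 * 0.8 * 0.2)
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert df == 0

    def test_calibrated_model_rejection_rate_nominal(self):
        # the g-2 degrees of freedom are calibrated for probabilities coming
        # from a fitted well-specified model, so fit one per replicate
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 200
        n = 1000
        for _ in range(n_rep):
            x = rng.normal(size=n)
            eta = -0.3 + 1.2 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            fit = fit_logistic(x, y)
            probs = 1 / (1 + np.exp(-(fit.params.iloc[0] + fit.params.iloc[1] * x)))
            _, _, p, _ = hosmer_lemeshow(probs, y, g=10)
            if p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.10


class TestCalibrationCurve:
    def test_five_bins_of_twenty(self):
        rng = np.random.default_rng(7)
        probs = rng.uniform(size=100)
        labels = (rng.random(100) < probs).astype(int)
        table = calibration_curve(probs, labels, bins=5)
        assert len(table) == 5 and (table.n == 20).all()

    def test_degenerate_probs_single_bin(self):
        probs = np.full(40, 0.5)
        labels = np.array([0, 1] * 20)
        table = calibration_curve(probs, labels, bins=5)
        assert len(table) == 1
        assert table.observed_rate.iloc[0] == pytest.approx(0.5)
        assert table.mean_predicted.iloc[0] == pytest.approx(0.5)

    def test_well_calibrated_points_near_identity(self):
        rng = np.random.default_rng(9)
        probs = rng.uniform(0.05, 0.95, 5000)
        labels = (rng.random(5000) < probs).astype(int)
        table = calibration_curve(probs, labels, bins=5)
        assert (abs(table.mean_predicted - table.observed_rate) < 0.05).all()


def _null_table(rng, n, n_candidates=2):
    df = pd.DataFrame(rng.normal(size=(n, n_candidates)),
                      columns=[f"f{i}" for i in range(n_candidates)])
    df["age"] = rng.normal(45, 10, n)
    df["sex"] = rng.choice(["female", "male"], n)
    df["label"] = rng.permutation(["PH"] * (n // 2) + ["HC"] * (n - n // 2))
    return df


class TestStepwise:
    def test_null_candidates_rarely_enter(self):
        # entry is a 1-df LR test at alpha = 0.05, so with a single null
        # candidate the entry rate should be near-nominal
        rng = np.random.default_rng(10)
        cfg = StepwiseConfig(candidate_terms=("f0",), scale_rules={})
        only_forced = 0
        n_rep = 50
        for _ in range(n_rep):
            res = StepwiseLogit(_null_table(rng, 200, n_candidates=1), cfg).fit()
            if res.selected_terms == ["age", "sex"]:
                only_forced += 1
        assert only_forced >= 0.9 * n_rep

    def test_informative_candidate_selected_first(self):
        rng = np.random.default_rng(11)
        cfg = StepwiseConfig(candidate_terms=("signal", "f0", "f1"), scale_rules={})
        for _ in range(20):
            df = _null_table(rng, 150)
            df["signal"] = (df.label == "PH").astype(float) * 2 + rng.normal(size=150)
            res = StepwiseLogit(df, cfg).fit()
            assert res.selected_terms[2] == "signal"

    def test_selection_invariant_to_affine_rescaling(self):
        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=120, n_ph=120, seed=21)))
        res1 = StepwiseLogit(table, StepwiseConfig(scale_rules={})).fit()
        res2 = StepwiseLogit(table, StepwiseConfig(scale_rules={"CA_R": 0.1})).fit()
        assert res1.selected_terms == res2.selected_terms
        if "CA_R" in res1.selected_terms:
            assert res2.params["CA_R"] == pytest.approx(res1.params["CA_R"] * 10, rel=1e-4)

    def test_collinear_screen_keeps_one_of_pair(self):
        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=150, n_ph=150, seed=11)))
        res = StepwiseLogit(table).fit()
        assert len({"CA_R", "FMA_R"} & set(res.dropped_terms)) == 1
        assert res.vif_table["CA_R"] > 5 and res.vif_table["FMA_R"] > 5


class TestBootstrapOptimism:
    def test_identity_resample_gives_zero_optimism(self, monkeypatch):
        import mcgkit.model as m

        class IdentityRng:
            def integers(self, lo, hi, size=None):
                return np.arange(size)

        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=40, n_ph=40, seed=5)))
        monkeypatch.setattr(m.np.random, "default_rng", lambda seed=None: IdentityRng())
        out = bootstrap_optimism(table, B=1, seed=0)
        assert out.optimism["auc"] == pytest.approx(0.0, abs=1e-12)
        assert out.corrected["auc"] == pytest.approx(out.apparent["auc"], abs=1e-12)

    def test_seeded_reproducibility(self):
        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=30, n_ph=30, seed=6)))
        cfg = StepwiseConfig(candidate_terms=("CA_R", "NCD_T"), scale_rules={})
        a = bootstrap_optimism(table, cfg, B=20, seed=42)
        b = bootstrap_optimism(table, cfg, B=20, seed=42)
        pd.testing.assert_frame_equal(a.per_resample, b.per_resample)

    def test_large_n_optimism_vanishes(self):
        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=400, n_ph=400, seed=7)))
        cfg = StepwiseConfig(candidate_terms=("CA_R", "NCD_T", "PD_R"), scale_rules={})
        out = bootstrap_optimism(table, cfg, B=30, seed=1)
        assert abs(out.corrected["auc"] - out.apparent["auc"]) < 0.02


class TestResultsSurface:
    def test_summary_and_serialization(self):
        table = records_to_frame(simulate_feature_table(CohortSpec(n_hc=100, n_ph=100, seed=14)))
        res = StepwiseLogit(table).fit()
        text = res.summary()
        assert "Youden cutoff" in text and "OR" in text
        d = res.to_dict()
        assert set(d["coefficients"]) == {"const", *res.selected_terms}
        assert 0 < d["cutoff"] < 1
        for term in res.selected_terms:
            assert d["odds_ratios"][term] == pytest.approx(math.exp(d["coefficients"][term]))
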