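"""Confounder screening, propensity fitting and stabilized IPTW estimation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from icpday.causal import (
    PSModelSpec,
    estimate_effect,
    fit_propensity,
    screen_confounders,
    stabilized_weights,
    standardized_mean_differences,
)
from icpday.simulate import simulate_confounded_binary


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestScreening:
    def test_planted_confounder_selected(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        t = (rng.uniform(size=n) < _expit(1.2 * x)).astype(int)
        y = (rng.uniform(size=n) < _expit(-1 + 0.8 * t + 1.0 * x)).astype(int)
        cov = pd.DataFrame({"x": x, "noise": noise})
        spec = PSModelSpec(candidate_covariates=("x", "noise"))
        selected, log = screen_confounders(cov, t, y, spec)
        assert "x" in selected
        assert set(log["covariate"]) == {"x", "noise"}

    def test_independent_covariate_usually_excluded(self):
        rng = np.random.default_rng(5)
        excluded = 0
        reps = 40
        for _ in range(reps):
            n = 2000
            t = (rng.uniform(size=n) < 0.4).astype(int)
            y = (rng.uniform(size=n) < 0.2).astype(int)
            cov = pd.DataFrame({"junk": rng.standard_normal(n)})
            sel, _ = screen_confounders(cov, t, y, PSModelSpec(candidate_covariates=("junk",)))
            excluded += "junk" not in sel
        assert excluded / reps >= 0.85

    def test_constant_covariate_skipped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 200
        cov = pd.DataFrame({"flat": np.ones(n)})
        with pytest.warns(UserWarning, match="constant"):
            sel, log = screen_confounders(
                cov, rng.integers(0, 2, n), rng.integers(0, 2, n),
                PSModelSpec(candidate_covariates=("flat",)),
            )
        assert sel == []


class TestPropensity:
    def test_no_covariates_gives_marginal_prevalence(self):
        t = np.array([1, 1, 0, 0, 0])
        ps = fit_propensity(pd.DataFrame(index=range(5)), t,
                            PSModelSpec(candidate_covariates=()))
        assert np.allclose(ps, 0.4)

    def test_recovers_known_logistic_rule(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.standard_normal(n)
        true_ps = _expit(0.3 + 1.1 * x)
        t = (rng.uniform(size=n) < true_ps).astype(int)
        cov = pd.DataFrame({"x": x})
        ps = fit_propensity(cov, t, PSModelSpec(candidate_covariates=("x",)))
        assert np.corrcoef(ps, true_ps)[0, 1] > 0.95

    def test_smooth_and_linear_agree_when_truth_linear(self):
        rng = np.random.default_rng(13)
        n = 2000
        x = rng.standard_normal(n)
        t = (rng.uniform(size=n) < _expit(0.8 * x)).astype(int)
        cov = pd.DataFrame({"x": x})
        ps_s = fit_propensity(cov, t, PSModelSpec(candidate_covariates=("x",), smoother=True))
        ps_l = fit_propensity(cov, t, PSModelSpec(candidate_covariates=("x",), smoother=False))
        assert np.sqrt(np.mean((ps_s - ps_l) ** 2)) < 0.05

    def test_separation_falls_back_with_warning(self):
        x = np.linspace(-2, 2, 40)
        t = (x > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            ps = fit_propensity(pd.DataFrame({"x": x}), t,
                                PSModelSpec(candidate_covariates=("x",), smoother=False))
        assert ((ps >= 0.01) & (ps <= 0.99)).all()

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            fit_propensity(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1, 1]))


class TestWeights:
    def test_marginal_ps_gives_unit_ate_weights(self):
        t = np.array([1, 1, 0, 0])
        w = stabilized_weights(np.full(4, 0.5), t, "ATE")
        assert np.allclose(w, 1.0)

    def test_ate_weight_arithmetic(self):
        w = stabilized_weights(np.array([0.25, 0.5]), np.array([1, 0]), "ATE")
        assert w[0] == pytest.approx(0.5 / 0.25)  # prevalence 0.5 over ps 0.25

    def test_att_treated_weights_are_one(self):
        rng = np.random.default_rng(17)
        ps = rng.uniform(0.1, 0.9, 50)
        t = rng.integers(0, 2, 50)
        w = stabilized_weights(ps, t, "ATT")
        assert np.allclose(w[t == 1], 1.0)
        assert np.allclose(w[t == 0], ps[t == 0] / (1 - ps[t == 0]))

    def test_stabilized_ate_weights_sum_near_n(self):
        df = simulate_confounded_binary(1000, np.log(2), seed=19)
        spec = PSModelSpec(candidate_covariates=("x1", "x2"), smoother=False)
        ps = fit_propensity(df[["x1", "x2"]], df["treatment"], spec)
        w = stabilized_weights(ps, df["treatment"], "ATE")
        assert abs(w.sum() - len(df)) / len(df) < 0.10

    def test_degenerate_ps_rejected(self):
        with pytest.raises(ValueError):
            stabilized_weights(np.array([0.0, 0.5]), np.array([1, 0]), "ATE")
        with pytest.raises(ValueError):
            stabilized_weights(np.array([0.5, 0.5]), np.array([1, 0]), "ATX")


class TestEffect:
    def test_unweighted_or_matches_2x2_arithmetic(self):
        # 13/22 treated deaths vs 26/154 control deaths: OR = 13*128/(9*26)
        y = np.array([1] * 13 + [0] * 9 + [1] * 26 + [0] * 128)
        t = np.array([1] * 22 + [0] * 154)
        est = estimate_effect(y, t, weights=np.ones(176), n_boot=50, seed=0)
        assert est.estimate == pytest.approx(13 * 128 / (9 * 26), rel=1e-6)

    def test_estimands_coincide_under_randomized_treatment(self):
        rng = np.random.default_rng(23)
        n = 400
        t = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        ests = {}
        for estimand in ("ATT", "ATU", "ATE"):
            w = stabilized_weights(np.full(n, t.mean()), t, estimand)
            ests[estimand] = estimate_effect(y, t, weights=w, n_boot=30, seed=1).estimate
        assert ests["ATT"] == pytest.approx(ests["ATU"], rel=1e-9)
        assert ests["ATT"] == pytest.approx(ests["ATE"], rel=1e-9)

    def test_weighting_balances_confounders(self):
        df = simulate_confounded_binary(2000, np.log(2), seed=29)
        w = stabilized_weights(df["true_ps"], df["treatment"], "ATE")
        smd_after = standardized_mean_differences(df[["x1", "x2"]], df["treatment"], w)
        smd_before = standardized_mean_differences(df[["x1", "x2"]], df["treatment"])
        assert (smd_after < 0.1).all()
        assert (smd_after < smd_before).all()

    def test_zero_event_arm_continuity_corrected(self):
        y = np.array([0] * 20 + [1] * 5 + [0] * 15)
        t = np.array([1] * 20 + [0] * 20)
        with pytest.warns(UserWarning, match="continuity"):
            est = estimate_effect(y, t, weights=np.ones(40), n_boot=30, seed=3)
        assert est.estimate > 0

    def test_recovers_planted_effect_with_bootstrap_ci(self):
        df = simulate_confounded_binary(2000, np.log(3.0), seed=31)
        p1, p0 = df["p_treated"].mean(), df["p_control"].mean()
        or_true = (p1 / (1 - p1)) / (p0 / (1 - p0))
        spec = PSModelSpec(candidate_covariates=("x1", "x2"), smoother=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = estimate_effect(
                df["outcome"], df["treatment"], covariates=df[["x1", "x2"]],
                spec=spec, estimand="ATE", n_boot=200, seed=5,
            )
        assert est.ci_low <= or_true <= est.ci_high
        assert est.ci_low <= est.estimate <= est.ci_high
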