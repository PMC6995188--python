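"""Rejection-set distributions and the eleven operating characteristics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal as scipy_mvn
from scipy.stats import norm

import polyarm as pa
from polyarm.corrections import thresholds
from polyarm.model import Design, EffectScenario, null_covariance, z_loadings
from polyarm.mvnorm import cov_from_loadings
from polyarm.opchar import (opchar_curve, opchar_from_distribution,
                            operating_characteristics,
                            rejection_distribution)
from polyarm.simulate import opchar_max_abs_diff, simulate_trial_opchars

UNIT2 = pa.NormalOutcome((1.0, 1.0, 1.0))


def unit_design(K, n=100.0):
    return Design(n0=n, ratios=(1.0,) * K)


class TestRejectionDistribution:
    def test_k1_no_correction_under_null(self):
        d = unit_design(1)
        thr = thresholds("none", 0.1, 1)
        dist = rejection_distribution(d, pa.NormalOutcome((1.0, 1.0)),
                                      EffectScenario.global_null(1), thr)
        assert dist.probs[frozenset({1})] == pytest.approx(0.1, abs=1e-9)
        assert dist.probs[frozenset()] == pytest.approx(0.9, abs=1e-9)

    def test_single_step_matches_scipy_genz_cdf(self):
        # dual route: our one-factor quadrature vs scipy's Genz algorithm
        d = Design(n0=90.0, ratios=(0.8, 1.4))
        model = pa.NormalOutcome((1.2, 0.9, 1.5))
        sc = EffectScenario.custom([0.25, 0.1])
        thr = thresholds("bonferroni", 0.1, 2)
        dist = rejection_distribution(d, model, sc, thr)
        eta, c = z_loadings(d, model, sc)
        cov = cov_from_loadings(c)
        zc = norm.ppf(1 - thr.gammas[0])
        p_none = scipy_mvn.cdf(zc - eta, mean=[0, 0], cov=cov,
                               abseps=1e-10, releps=0)
        assert dist.probs[frozenset()] == pytest.approx(p_none, abs=1e-7)
        # both rejected, via inclusion-exclusion on univariate tails
        p1 = 1 - norm.cdf(zc - eta[0])
        p2 = 1 - norm.cdf(zc - eta[1])
        p_both = p1 + p2 - (1 - p_none)
        assert dist.probs[frozenset({1, 2})] == pytest.approx(p_both, abs=1e-7)

    @pytest.mark.parametrize("mcc", list(pa.model.MCCS))
    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_probabilities_sum_to_one(self, mcc, K, rng):
        # randomised PD one-factor covariances and effects
        sig = tuple(rng.uniform(0.5, 2.0, K + 1))
        ns = rng.uniform(30, 150, K)
        d = Design(n0=float(rng.uniform(30, 150)),
                   ratios=tuple(ns / 100))
        model = pa.NormalOutcome(sig)
        sc = EffectScenario.custom(rng.uniform(-0.3, 0.6, K))
        if mcc == "stepdown_dunnett":
            d = unit_design(K, 75.0)
            model = pa.NormalOutcome((1.0,) * (K + 1))
        cov = null_covariance_for(d, model)
        thr = thresholds(mcc, 0.1, K, covariance=cov)
        dist = rejection_distribution(d, model, sc, thr)
        assert sum(dist.probs.values()) == pytest.approx(1.0, abs=1e-6)

    def test_stepwise_matches_simulation(self, rng):
        d = Design(n0=80.0, ratios=(1.0, 1.3, 0.7))
        model = pa.NormalOutcome((1.0, 1.1, 0.8, 1.2))
        sc = EffectScenario.custom([0.3, 0.0, 0.15])
        for mcc in ("holm_bonferroni", "hochberg", "benjamini_hochberg"):
            thr = thresholds(mcc, 0.1, 3)
            dist = rejection_distribution(d, model, sc, thr)
            sim = simulate_trial_opchars(d, model, sc, thr, 10 ** 5,
                                         int(rng.integers(2 ** 31)))
            analytic = opchar_from_distribution(dist, sc.tau)
            diff = opchar_max_abs_diff(analytic, sim.opchar_hat)
            assert diff < 5e-3, (mcc, diff)

    def test_holm_respects_fwer_bound_under_null(self):
        d = unit_design(2)
        thr = thresholds("holm_bonferroni", 0.05, 2)
        dist = rejection_distribution(d, UNIT2,
                                      EffectScenario.global_null(2), thr)
        p_any = 1 - dist.probs[frozenset()]
        assert p_any <= 0.05 + 1e-9

    def test_qmc_path_close_to_simulation(self, rng):
        d = unit_design(4, 60.0)
        model = pa.NormalOutcome((1.0,) * 5)
        sc = EffectScenario.custom([0.3, 0.3, 0.0, 0.0])
        thr = thresholds("hochberg", 0.1, 4)
        with pytest.warns(RuntimeWarning):
            dist = rejection_distribution(d, model, sc, thr)
        assert sum(dist.probs.values()) == pytest.approx(1.0, abs=1e-9)
        analytic = opchar_from_distribution(dist, sc.tau)
        sim = simulate_trial_opchars(d, model, sc, thr, 2 * 10 ** 5,
                                     int(rng.integers(2 ** 31)))
        assert opchar_max_abs_diff(analytic, sim.opchar_hat) < 5e-3


def null_covariance_for(design, model):
    _, cov = pa.z_distribution(design, model,
                               EffectScenario.global_null(design.K))
    return cov


class TestOperatingCharacteristics:
    def test_k1_closed_form_power(self):
        # two-arm z-test power: P_con = P_dis = P_1 = Phi(delta sqrt(I) - z_{1-a})
        d = unit_design(1, 85.0)
        model = pa.NormalOutcome((1.0, 1.0))
        sc = EffectScenario.custom([0.5])
        thr = thresholds("none", 0.025, 1)
        oc = operating_characteristics(d, model, sc, thr)
        info = 1 / (2 / 85)
        expected = norm.cdf(0.5 * np.sqrt(info) - norm.ppf(0.975))
        for val in (oc.p_con, oc.p_dis, oc.p_marginal[0]):
            assert val == pytest.approx(expected, abs=1e-9)

    def test_dunnett_attains_alpha_exactly(self, rng):
        # single-step Dunnett: FWER_I1 = alpha under H_G by construction
        for K in (1, 2, 3):
            alpha = float(rng.uniform(0.02, 0.2))
            sig = tuple(rng.uniform(0.5, 2.0, K + 1))
            d = Design(n0=100.0, ratios=tuple(rng.uniform(0.5, 2.0, K)))
            model = pa.NormalOutcome(sig)
            cov = null_covariance_for(d, model)
            thr = thresholds("dunnett", alpha, K, covariance=cov)
            oc = operating_characteristics(
                d, model, EffectScenario.global_null(K), thr)
            assert oc.fwer_i[0] == pytest.approx(alpha, abs=1e-6)

    def test_strong_fwer_control_on_tau_grid(self):
        d = unit_design(2, 80.0)
        cov = null_covariance_for(d, UNIT2)
        for mcc in ("bonferroni", "holm_bonferroni", "hochberg",
                    "stepdown_dunnett"):
            thr = thresholds(mcc, 0.1, 2, covariance=cov)
            for t1 in (-0.3, 0.0, 0.4):
                for t2 in (-0.3, 0.0, 0.4):
                    sc = EffectScenario.custom([t1, t2])
                    oc = operating_characteristics(d, UNIT2, sc, thr)
                    true_nulls = sum(t <= 0 for t in (t1, t2))
                    if true_nulls:
                        assert oc.fwer_i[0] <= 0.1 + 1e-7, (mcc, t1, t2)

    def test_bh_controls_fdr_on_mixed_grid(self):
        d = unit_design(3, 70.0)
        model = pa.NormalOutcome((1.0,) * 4)
        thr = thresholds("benjamini_hochberg", 0.1, 3)
        grid = (-0.3, 0.0, 0.35)
        for t1 in grid:
            for t2 in grid:
                for t3 in grid:
                    sc = EffectScenario.custom([t1, t2, t3])
                    oc = operating_characteristics(d, model, sc, thr)
                    assert oc.fdr <= 0.1 + 1e-7

    def test_power_ordering_invariant(self):
        d = unit_design(2, 90.0)
        thr = thresholds("holm_bonferroni", 0.1, 2)
        sc = EffectScenario.custom([0.3, 0.1])
        oc = operating_characteristics(d, UNIT2, sc, thr)
        assert oc.p_con <= min(oc.p_marginal) + 1e-12
        assert max(oc.p_marginal) <= oc.p_dis + 1e-12
        assert np.all(np.diff(oc.fwer_i) <= 1e-12)
        assert np.all(np.diff(oc.fwer_ii) <= 1e-12)

    def test_fdr_equals_fwer_under_global_null(self):
        d = unit_design(2, 90.0)
        thr = thresholds("sidak", 0.1, 2)
        oc = operating_characteristics(d, UNIT2,
                                       EffectScenario.global_null(2), thr)
        assert oc.fdr == pytest.approx(oc.fwer_i[0], abs=1e-12)
        assert np.isnan(oc.sensitivity)  # no false nulls under H_G
        assert oc.pfdr == pytest.approx(1.0, abs=1e-9)

    def test_example_design_symmetries(self, example_bernoulli_spec,
                                       example_bernoulli_result):
        spec, res = example_bernoulli_spec, example_bernoulli_result
        d = res.design
        oc_g = operating_characteristics(d, spec.outcome,
                                         spec.scenario("H_G"),
                                         res.thresholds)
        assert oc_g.fwer_i[0] == pytest.approx(0.15, abs=1e-6)
        oc1 = operating_characteristics(d, spec.outcome,
                                        spec.scenario("LFC_1"),
                                        res.thresholds)
        oc2 = operating_characteristics(d, spec.outcome,
                                        spec.scenario("LFC_2"),
                                        res.thresholds)
        # equal allocation: P_con and P_dis equal across the LFCs, P_1 = P_2
        assert oc1.p_con == pytest.approx(oc2.p_con, abs=1e-9)
        assert oc1.p_dis == pytest.approx(oc2.p_dis, abs=1e-9)
        assert oc1.p_marginal[0] == pytest.approx(oc2.p_marginal[1], abs=1e-9)


class TestCurves:
    def test_shifted_all_reproduces_named_scenarios(self, example_normal_spec,
                                                    example_normal_result):
        spec, res = example_normal_spec, example_normal_result
        d = res.final_design
        curve = opchar_curve(d, spec.outcome, spec, res.thresholds,
                             [0.0, spec.delta1], mode="shifted_all")
        oc_g = operating_characteristics(d, spec.outcome,
                                         spec.scenario("H_G"),
                                         res.thresholds)
        oc_a = operating_characteristics(d, spec.outcome,
                                         spec.scenario("H_A"),
                                         res.thresholds)
        assert curve.loc[0, "FWER_I1"] == pytest.approx(oc_g.fwer_i[0])
        assert curve.loc[1, "P_con"] == pytest.approx(oc_a.p_con)

    def test_shifted_one_reproduces_lfc_marginals(self, example_normal_spec,
                                                  example_normal_result):
        spec, res = example_normal_spec, example_normal_result
        d = res.final_design
        curve = opchar_curve(d, spec.outcome, spec, res.thresholds,
                             [spec.delta1], mode="shifted_one")
        oc1 = operating_characteristics(d, spec.outcome,
                                        spec.scenario("LFC_1"),
                                        res.thresholds)
        assert curve.loc[0, "P_1"] == pytest.approx(oc1.p_marginal[0])

    def test_bernoulli_grid_outside_unit_interval_raises(
            self, example_bernoulli_spec, example_bernoulli_result):
        spec, res = example_bernoulli_spec, example_bernoulli_result
        with pytest.raises(pa.InvalidDesignError):
            opchar_curve(res.design, spec.outcome, spec, res.thresholds,
                         [0.9], mode="shifted_all")
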