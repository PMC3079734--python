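"""Binormal ROC machinery: AUC estimators, optimal combinations, panels."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from csfpanels import (
    bootstrap_evaluate,
    direction_auc,
    empirical_auc,
    empirical_sensitivity_at_specificity,
    expand_panels,
    fit_binormal,
    optimal_combination,
    sensitivity_at_specificity,
)


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert empirical_auc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert empirical_auc(np.ones(10), np.r_[np.zeros(5), np.ones(5)]) == 0.5

    def test_five_v_five_matches_exhaustive_pair_count(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.5, 0.45, 0.6, 0.35, 0.9, 0.2])
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert empirical_auc(scores, labels) == pytest.approx(brute, rel=1e-15)

    def test_raw_orientation_can_fall_below_half(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert empirical_auc(scores, labels) == 0.0
        assert empirical_auc(scores, labels, orient=True) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc(np.arange(5.0), np.ones(5))


class TestFitBinormal:
    def test_single_marker_study_summaries_stored_exactly(self):
        """Group moments matching published CSF tau summary statistics
        (means 315/547, SDs 169/278) are stored as given."""
        rng = np.random.default_rng(0)

        def with_moments(n, mean, sd):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        x = np.r_[with_moments(242, 315.0, 169.0), with_moments(91, 547.0, 278.0)]
        labels = np.r_[np.zeros(242), np.ones(91)]
        model = fit_binormal(x, ["tau"], labels)
        assert model.mu0[0] == pytest.approx(315.0)
        assert model.mu1[0] == pytest.approx(547.0)
        assert np.sqrt(model.sigma0[0, 0]) == pytest.approx(169.0)
        assert np.sqrt(model.sigma1[0, 0]) == pytest.approx(278.0)
        assert model.auc == pytest.approx(norm.cdf(232 / np.hypot(169, 278)), rel=1e-12)

    def test_identical_groups_have_zero_delta(self):
        x = np.tile(np.arange(10.0), 2)[:, None] + np.random.default_rng(1).normal(0, 1e-6, (20, 1))
        labels = np.r_[np.zeros(10), np.ones(10)]
        model = fit_binormal(x, ["m"], labels)
        assert model.delta[0] == pytest.approx(0.0, abs=1e-5)

    def test_moments_match_hand_computation_on_six_subjects(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0],
                      [4.0, 6.0], [6.0, 5.0], [5.0, 7.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        model = fit_binormal(pd.DataFrame(X, columns=["a", "b"]), ["a", "b"], labels)
        assert model.mu0 == pytest.approx(X[:3].mean(axis=0))
        assert model.sigma1 == pytest.approx(np.cov(X[3:].T, ddof=1))


class TestOptimalCombination:
    def test_symmetric_identity_case(self):
        a, auc = optimal_combination([0, 0], [1, 1], np.eye(2), np.eye(2))
        assert a == pytest.approx(np.array([1, 1]) / np.sqrt(2))
        assert auc == pytest.approx(norm.cdf(1.0), rel=1e-12)

    def test_single_marker_reduces_to_phi_of_standardized_delta(self):
        a, auc = optimal_combination([315.0], [547.0], [[169.0 ** 2]], [[278.0 ** 2]])
        assert auc == pytest.approx(norm.cdf(232 / np.sqrt(169 ** 2 + 278 ** 2)), rel=1e-12)
        assert auc == pytest.approx(0.76, abs=0.005)

    def test_closed_form_beats_random_directions(self):
        """On random 3-marker instances the closed form attains the maximal
        analytic AUC over thousands of random unit directions."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = 3
            L0, L1 = rng.standard_normal((p, p)), rng.standard_normal((p, p))
            s0, s1 = L0 @ L0.T + 0.5 * np.eye(p), L1 @ L1.T + 0.5 * np.eye(p)
            mu0, mu1 = rng.standard_normal(p), rng.standard_normal(p)
            a, auc = optimal_combination(mu0, mu1, s0, s1)
            from csfpanels import BinormalModel
            m = BinormalModel(["x"] * p, np.asarray(mu0), np.asarray(mu1),
                              s0, s1, a, auc)
            u = rng.standard_normal((2000, p))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            best = max(direction_auc(m, ui) for ui in u)
            assert auc >= best - 1e-9

    def test_singular_sum_raises_with_ridge_advice(self):
        s = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError):
            optimal_combination([0, 0], [1, 1], s, s)


class TestSensitivityAtSpecificity:
    def make_model(self, mu0, mu1, s0, s1):
        from csfpanels import BinormalModel
        a, auc = optimal_combination(mu0, mu1, s0, s1)
        return BinormalModel(["m"] * len(np.atleast_1d(mu0)),
                             np.atleast_1d(np.asarray(mu0, float)),
                             np.atleast_1d(np.asarray(mu1, float)),
                             np.atleast_2d(s0), np.atleast_2d(s1), a, auc)

    def test_identical_groups_give_diagonal_roc(self):
        m = self.make_model([0.0], [0.0], [[1.0]], [[1.0]])
        assert sensitivity_at_specificity(m, 0.80) == pytest.approx(0.20, rel=1e-9)

    def test_large_separation_approaches_one(self):
        m = self.make_model([0.0], [50.0], [[1.0]], [[1.0]])
        assert sensitivity_at_specificity(m, 0.80) > 0.9999

    def test_invalid_specificity_rejected(self):
        m = self.make_model([0.0], [1.0], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            sensitivity_at_specificity(m, 1.0)

    def test_binormal_formula_matches_monte_carlo(self):
        """Analytic sensitivity at 80% specificity agrees with the
        empirical ROC of 100k simulated binormal subjects within 0.005."""
        rng = np.random.default_rng(3)
        mu0, mu1 = np.array([0.0, 0.0]), np.array([1.0, 0.5])
        s0 = np.array([[1.0, 0.3], [0.3, 1.0]])
        s1 = np.array([[1.5, 0.2], [0.2, 1.2]])
        m = self.make_model(mu0, mu1, s0, s1)
        n = 100_000
        x0 = rng.multivariate_normal(mu0, s0, n)
        x1 = rng.multivariate_normal(mu1, s1, n)
        scores = np.r_[x0 @ m.a, x1 @ m.a]
        labels = np.r_[np.zeros(n), np.ones(n)]
        emp = empirical_sensitivity_at_specificity(scores, labels, 0.80)
        assert sensitivity_at_specificity(m, 0.80) == pytest.approx(emp, abs=0.005)


class TestExpandPanels:
    def test_study_layout_yields_39_unique_panels(self):
        """Four 2-marker bases x ten candidates, with one candidate already
        inside one base, leaves 10+10+10+9 = 39 panels."""
        bases = [("ratio", "cysC"), ("ratio", "vegf"),
                 ("ratio", "kim1"), ("ratio", "pp")]
        candidates = ["trailr3", "pai1", "pp", "ntprobnp", "mmp10",
                      "mif", "groa", "fib", "fas", "eot3"]
        panels = expand_panels(bases, candidates, 4, 10)
        assert len(panels) == 39
        assert len({frozenset(p) for p in panels}) == 39
        assert all(len(set(p)) == 3 for p in panels)

    def test_single_base_single_candidate(self):
        assert expand_panels([("a", "b")], ["c"], 1, 1) == [("a", "b", "c")]

    def test_candidates_equal_to_base_members_give_empty(self):
        assert expand_panels([("a", "b")], ["a", "b"], 1, 2) == []


class TestBootstrapEvaluate:
    def make_data(self, n0=120, n1=60, delta=(1.2, 0.8, 0.5), seed=4):
        rng = np.random.default_rng(seed)
        p = len(delta)
        x0 = rng.standard_normal((n0, p))
        x1 = rng.standard_normal((n1, p)) + np.asarray(delta)
        values = pd.DataFrame(np.vstack([x0, x1]), columns=["m1", "m2", "m3"])
        labels = np.r_[np.zeros(n0), np.ones(n1)]
        return values, labels

    def test_identical_panels_have_unit_pvalue(self):
        values, labels = self.make_data()
        ev = bootstrap_evaluate(values, labels, ("m1", "m2"), ("m1", "m2"),
                                B=10, seed=0)
        assert ev.p_mean == 1.0 and ev.p_sd == 0.0

    def test_same_seed_reproduces_evaluation(self):
        values, labels = self.make_data()
        e1 = bootstrap_evaluate(values, labels, ("m1", "m2", "m3"), ("m1", "m2"),
                                B=25, seed=9)
        e2 = bootstrap_evaluate(values, labels, ("m1", "m2", "m3"), ("m1", "m2"),
                                B=25, seed=9)
        assert e1 == e2

    def test_strong_signal_auc_recovered(self):
        """With a known true optimal AUC of ~0.9 the bootstrap mean lands
        within 0.03 of the constructed value."""
        rng = np.random.default_rng(10)
        target = 0.90
        d = norm.ppf(target) * np.sqrt(2)  # single effective direction
        n0 = n1 = 300
        x0 = rng.standard_normal((n0, 2))
        x1 = rng.standard_normal((n1, 2))
        x1[:, 0] += d
        values = pd.DataFrame(np.vstack([x0, x1]), columns=["m1", "m2"])
        labels = np.r_[np.zeros(n0), np.ones(n1)]
        ev = bootstrap_evaluate(values, labels, ("m1", "m2"), ("m1",), B=60, seed=11)
        assert ev.auc_mean == pytest.approx(target, abs=0.03)

    def test_no_signal_panel_stays_near_chance(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(rng.standard_normal((333, 3)),
                              columns=["m1", "m2", "m3"])
        labels = np.r_[np.zeros(242), np.ones(91)]
        ev = bootstrap_evaluate(values, labels, ("m1", "m2", "m3"), ("m1", "m2"),
                                B=40, seed=13)
        assert 0.45 <= ev.auc_mean <= 0.60
        assert ev.p_mean > 0.2

    def test_nested_analytic_auc_is_monotone(self):
        """Adding a marker never decreases the in-sample analytic AUC."""
        values, labels = self.make_data(seed=14)
        for sub, full in [(("m1",), ("m1", "m2")), (("m1", "m2"), ("m1", "m2", "m3"))]:
            m_sub = fit_binormal(values, list(sub), labels)
            m_full = fit_binormal(values, list(full), labels)
            assert m_full.auc >= m_sub.auc - 1e-12

    def test_non_nested_reduction_rejected(self):
        values, labels = self.make_data()
        with pytest.raises(ValueError, match="nested"):
            bootstrap_evaluate(values, labels, ("m1", "m2"), ("m3",), B=5)

    def test_tiny_b_rejected(self):
        values, labels = self.make_data()
        with pytest.raises(ValueError):
            bootstrap_evaluate(values, labels, ("m1",), ("m1",), B=1)
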