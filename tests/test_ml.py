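"""Resampling harness, reference classifiers, and importance overlap."""

import numpy as np
import pandas as pd
import pytest

from csfpanels import (
    ImportanceRanking,
    KNearestNeighbors,
    NaiveBayes,
    NearestShrunkenCentroids,
    importance_overlap,
    resample_evaluate,
    youden_index,
)
from csfpanels.ml import _stratified_split


class TestYouden:
    @pytest.mark.parametrize("sens,spec,expected", [
        (0.845, 0.776, 0.621),
        (0.872, 0.566, 0.438),
        (1.0, 1.0, 1.0),
        (0.5, 0.5, 0.0),
    ])
    def test_arithmetic(self, sens, spec, expected):
        assert youden_index(sens, spec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sens,spec", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, sens, spec):
        with pytest.raises(ValueError):
            youden_index(sens, spec)


class OracleClassifier:
    """Scores equal to the (leaked) first predictor column == true label."""

    name = "oracle"

    def fit(self, X, y, rng=None):
        return self

    def predict_scores(self, X):
        return X[:, 0]


class ConstantClassifier:
    name = "const"

    def fit(self, X, y, rng=None):
        return self

    def predict_scores(self, X):
        return np.full(len(X), 0.5)


class TestResampleEvaluate:
    def make_xy(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
        X = pd.DataFrame({"leak": y.astype(float),
                          "noise": rng.standard_normal(n)})
        return X, y

    def test_oracle_classifier_is_perfect(self):
        X, y = self.make_xy()
        res = resample_evaluate(OracleClassifier(), X, y, n_splits=10, seed=1)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.youden == 1.0 and res.auc == 1.0

    def test_constant_scores_are_chance(self):
        X, y = self.make_xy()
        res = resample_evaluate(ConstantClassifier(), X, y, n_splits=10, seed=2)
        assert res.auc == 0.5
        # 0.5 score passes the >= 0.5 cut: everything called positive
        assert res.sensitivity == 1.0 and res.specificity == 0.0
        assert res.youden == pytest.approx(0.0)

    def test_seeded_run_is_reproducible(self):
        X, y = self.make_xy()
        r1 = resample_evaluate(NaiveBayes(), X, y, n_splits=8, seed=3)
        r2 = resample_evaluate(NaiveBayes(), X, y, n_splits=8, seed=3)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split)

    def test_youden_identity_on_every_row(self):
        X, y = self.make_xy(seed=4)
        res = resample_evaluate(NaiveBayes(), X, y, n_splits=12, seed=5)
        for _, row in res.per_split.iterrows():
            assert row["youden"] == pytest.approx(
                row["sensitivity"] + row["specificity"] - 1)
        assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1)

    def test_stratified_splits_preserve_class_ratio(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.zeros(73), np.ones(27)].astype(int)
        for _ in range(20):
            tr, te = _stratified_split(y, 0.8, rng)
            assert abs((y[tr] == 1).sum() - round(0.8 * 27)) <= 1
            assert abs((y[te] == 0).sum() - round(0.2 * 73)) <= 1
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 100


class TestNSC:
    def make_toy(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = rng.standard_normal((n, 3))
        X[y == 1, 0] += 2.0
        X[y == 1, 1] += 0.5
        return X, y

    def test_zero_threshold_is_plain_nearest_centroid(self):
        """At shrinkage 0 with balanced classes, predictions equal nearest
        centroid in the (s + s0)-standardized feature space."""
        X, y = self.make_toy()
        clf = NearestShrunkenCentroids(threshold=0.0).fit(X, y)
        params = clf.params_
        scale = params["s"] + params["s0"]
        cent = np.vstack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        d0 = (((X - cent[0]) / scale) ** 2).sum(axis=1)
        d1 = (((X - cent[1]) / scale) ** 2).sum(axis=1)
        expected = (d1 < d0).astype(int)
        assert ((clf.predict_scores(X) >= 0.5).astype(int) == expected).all()

    def test_saturating_threshold_predicts_prior_class(self):
        X, y = self.make_toy()
        y_unbal = y.copy()
        y_unbal[:40] = 0  # priors 40:20
        clf = NearestShrunkenCentroids(threshold=1e6).fit(X, y_unbal)
        assert (clf.params_["d_shrunk"] == 0).all()
        pred = (clf.predict_scores(X) >= 0.5).astype(int)
        assert (pred == 0).all()  # majority class everywhere

    def test_shrunken_centroids_match_soft_threshold_formula(self):
        """2-class 3-feature toy: centroids equal the hand-applied
        soft-thresholding of standardized centroid differences."""
        X, y = self.make_toy()
        delta = 0.8
        clf = NearestShrunkenCentroids(threshold=delta).fit(X, y)
        p = clf.params_
        n, nk = len(y), np.array([30, 30])
        overall = X.mean(axis=0)
        cent = np.vstack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        within = sum(((X[y == k] - cent[k]) ** 2).sum(axis=0) for k in (0, 1))
        s = np.sqrt(within / (n - 2))
        s0 = np.median(s)
        mk = np.sqrt(1 / nk - 1 / n)
        d = (cent - overall) / (mk[:, None] * (s + s0))
        d_sh = np.sign(d) * np.maximum(np.abs(d) - delta, 0)
        expected = overall + mk[:, None] * (s + s0) * d_sh
        assert p["centroids"] == pytest.approx(expected, rel=1e-12)

    def test_importance_ranks_strong_feature_first(self):
        X, y = self.make_toy()
        clf = NearestShrunkenCentroids(threshold=0.5).fit(X, y)
        imp = clf.importance(["f0", "f1", "f2"])
        assert imp.iloc[0]["predictor"] == "f0"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            NearestShrunkenCentroids(threshold=-1.0)


class TestKNN:
    def test_k1_has_perfect_training_recall(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 2))
        y = (rng.random(30) < 0.5).astype(int)
        clf = KNearestNeighbors(k=1).fit(X, y)
        assert ((clf.predict_scores(X) >= 0.5).astype(int) == y).all()

    def test_k_exceeding_training_size_rejected(self):
        X = np.zeros((5, 1))
        y = np.array([0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            KNearestNeighbors(k=10).fit(X, y)

    def test_score_is_vote_fraction(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        y = np.array([0, 0, 1, 1, 1])
        clf = KNearestNeighbors(k=3).fit(X, y)
        # point near the low cluster: neighbours are the three low points
        assert clf.predict_scores(np.array([[0.05]]))[0] == pytest.approx(1 / 3)


class TestNaiveBayes:
    def test_single_feature_matches_closed_form_posterior(self):
        rng = np.random.default_rng(9)
        n = 2000
        y = np.r_[np.zeros(n), np.ones(n)].astype(int)
        x = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        clf = NaiveBayes().fit(x[:, None], y)
        grid = np.linspace(-2, 4, 9)[:, None]
        scores = clf.predict_scores(grid)
        from scipy.stats import norm
        mu0, v0 = clf.mu_[0, 0], clf.var_[0, 0]
        mu1, v1 = clf.mu_[1, 0], clf.var_[1, 0]
        f0 = norm.pdf(grid[:, 0], mu0, np.sqrt(v0)) * clf.priors_[0]
        f1 = norm.pdf(grid[:, 0], mu1, np.sqrt(v1)) * clf.priors_[1]
        assert scores == pytest.approx(f1 / (f0 + f1), rel=1e-9)

    def test_kernel_bandwidth_to_infinity_recovers_priors(self):
        rng = np.random.default_rng(10)
        y = np.r_[np.zeros(30), np.ones(10)].astype(int)
        X = rng.standard_normal((40, 2))
        clf = NaiveBayes(kernel=True, bandwidth_factor=1e6).fit(X, y)
        scores = clf.predict_scores(rng.standard_normal((5, 2)))
        assert scores == pytest.approx(np.full(5, 0.25), abs=1e-3)


class TestImportanceOverlap:
    def rank(self, name, items):
        return ImportanceRanking(name, pd.DataFrame({
            "predictor": items,
            "importance": np.linspace(1, 0.1, len(items))}))

    def test_identical_rankings_overlap_fully(self):
        r = [self.rank("a", list("wxyz")), self.rank("b", list("wxyz"))]
        out = importance_overlap(r, k=4)
        assert out["pairwise"]["a|b"] == 4
        assert out["global_count"] == 4

    def test_disjoint_rankings_overlap_zero(self):
        r = [self.rank("a", list("abcd")), self.rank("b", list("wxyz"))]
        out = importance_overlap(r, k=4)
        assert out["pairwise"]["a|b"] == 0 and out["global_count"] == 0

    def test_three_rankings_match_exhaustive_set_arithmetic(self):
        lists = {"a": ["t", "u", "v", "w"], "b": ["t", "u", "x", "y"],
                 "c": ["t", "z", "v", "y"]}
        out = importance_overlap([self.rank(n, l) for n, l in lists.items()], k=4,
                                 reference_set=["t", "w", "x"])
        sets = {n: set(l) for n, l in lists.items()}
        assert out["pairwise"]["a|b"] == len(sets["a"] & sets["b"])
        assert out["pairwise"]["a|c"] == len(sets["a"] & sets["c"])
        assert out["pairwise"]["b|c"] == len(sets["b"] & sets["c"])
        assert set(out["global_intersection"]) == sets["a"] & sets["b"] & sets["c"]
        assert out["reference_overlap"]["a"] == len(sets["a"] & {"t", "w", "x"})

    def test_k_exceeding_length_rejected(self):
        r = [self.rank("a", list("ab")), self.rank("b", list("ab"))]
        with pytest.raises(ValueError):
            importance_overlap(r, k=5)

    def test_single_ranking_rejected(self):
        with pytest.raises(ValueError):
            importance_overlap([self.rank("a", list("ab"))], k=2)


class TestPredictorSetDirection:
    def test_extra_informative_markers_raise_nsc_youden(self):
        """With planted signal beyond a small core panel, the expanded
        predictor set attains at least the core set's mean Youden for the
        NSC model (directional pattern over seeds)."""
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 150
            y = np.r_[np.zeros(100), np.ones(50)].astype(int)
            core = rng.standard_normal((n, 2))
            core[y == 1, 0] += 0.8
            extra = rng.standard_normal((n, 6)) + 0.9 * y[:, None]
            X_core = pd.DataFrame(core, columns=["c0", "c1"])
            X_all = pd.DataFrame(np.hstack([core, extra]),
                                 columns=[f"p{j}" for j in range(8)])
            r_core = resample_evaluate(NearestShrunkenCentroids(), X_core, y,
                                       n_splits=8, seed=seed)
            r_all = resample_evaluate(NearestShrunkenCentroids(), X_all, y,
                                      n_splits=8, seed=seed)
            wins += r_all.youden >= r_core.youden
        assert wins >= n_seeds - 1
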