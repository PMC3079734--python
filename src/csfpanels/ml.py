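"""Model-agnostic repeated-split evaluation with native reference
classifiers (nearest shrunken centroids, k-nearest neighbours, naive
Bayes) and importance-overlap reporting.

The protocol: the cohort is repeatedly split into a stratified 80%
training / 20% test partition (200 times by default); any hyperparameter
is tuned by inner resampling of the training portion only; per-split
sensitivity, specificity (at the argmax-posterior operating point), the
Youden index, and the held-out AUC are averaged over splits. Age, gender,
and APOE epsilon-4 status are always appended to the predictor set.

External learners (random forests, boosted trees, SVM, ...) attach through
the :class:`SklearnAdapter` fit/score contract; only the three reference
classifiers are implemented natively, NSC with its built-in importance
statistic (the surviving features' absolute shrunken differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .roc import empirical_auc

logger = logging.getLogger("csfpanels")

#: shrinkage-threshold grid: 30 values spanning the working range
NSC_THRESHOLD_GRID = np.linspace(0.325, 9.097, 30)
#: candidate neighbour counts for k-NN
KNN_GRID = tuple(range(5, 16))


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    return sensitivity + specificity - 1


# ---------------------------------------------------------------------------
# Classifier contract
# ---------------------------------------------------------------------------

class Classifier(Protocol):
    name: str

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "Classifier": ...

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class score per row, in [0,1]; 0.5 is the class cut."""


def _stratified_split(y: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test indices preserving the class ratio within +/-1."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.append(idx[:n_tr])
        test.append(idx[n_tr:])
    return np.concatenate(train), np.concatenate(test)


def _inner_tune(scores_by_param: dict, grid: Sequence, prefer_larger: bool):
    """Pick the grid value with the best mean inner score; ties go to the
    more parsimonious (larger threshold / smaller k) choice."""
    best = None
    order = list(grid)[:: -1 if prefer_larger else 1]
    for g in order:
        s = float(np.mean(scores_by_param[g]))
        if best is None or s > best[1] + 1e-12:
            best = (g, s)
    return best[0]


# ---------------------------------------------------------------------------
# Nearest shrunken centroids
# ---------------------------------------------------------------------------

class NearestShrunkenCentroids:
    """Two-class nearest shrunken centroids with soft-thresholded
    standardized centroid differences and class-prior discriminants.

    With shrinkage 0 this is plain nearest-centroid classification; with a
    threshold exceeding every standardized difference all features shrink
    out and prediction falls back to the prior class.
    """

    name = "nsc"

    def __init__(self, threshold: float | None = None,
                 threshold_grid: Sequence[float] = NSC_THRESHOLD_GRID,
                 n_inner: int = 5):
        if threshold is not None and threshold < 0:
            raise ValueError("shrinkage threshold must be nonnegative")
        if any(t < 0 for t in threshold_grid):
            raise ValueError("shrinkage thresholds must be nonnegative")
        self.threshold = threshold
        self.threshold_grid = list(threshold_grid)
        self.n_inner = n_inner

    def _fit_at(self, X, y, threshold):
        n, p = X.shape
        classes = np.array([0, 1])
        overall = X.mean(axis=0)
        cent = np.vstack([X[y == c].mean(axis=0) for c in classes])
        nk = np.array([(y == c).sum() for c in classes])
        within_ss = sum(((X[y == c] - cent[k]) ** 2).sum(axis=0)
                        for k, c in enumerate(classes))
        s = np.sqrt(within_ss / (n - 2))
        s0 = np.median(s)
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        d = (cent - overall) / (mk[:, None] * (s + s0))
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - threshold, 0.0)
        cent_shrunk = overall + mk[:, None] * (s + s0) * d_shrunk
        return {
            "overall": overall, "s": s, "s0": s0,
            "centroids": cent_shrunk, "d_shrunk": d_shrunk,
            "priors": nk / n, "classes": classes,
        }

    def _score_with(self, params, X):
        denom = (params["s"] + params["s0"]) ** 2
        disc = np.empty((len(X), 2))
        for k in range(2):
            disc[:, k] = ((X - params["centroids"][k]) ** 2 / denom).sum(axis=1) \
                - 2 * np.log(params["priors"][k])
        # posterior-style score via the discriminant gap
        gap = np.clip((disc[:, 0] - disc[:, 1]) / 2.0, -500, 500)
        return 1.0 / (1.0 + np.exp(-gap))

    def fit(self, X, y, rng=None):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        if self.threshold is None:
            rng = rng if rng is not None else np.random.default_rng(0)
            acc = {t: [] for t in self.threshold_grid}
            for _ in range(self.n_inner):
                tr, te = _stratified_split(y, 0.8, rng)
                for t in self.threshold_grid:
                    params = self._fit_at(X[tr], y[tr], t)
                    pred = (self._score_with(params, X[te]) >= 0.5).astype(int)
                    acc[t].append(np.mean(pred == y[te]))
            self.threshold_ = _inner_tune(acc, self.threshold_grid, prefer_larger=True)
        else:
            self.threshold_ = self.threshold
        self.params_ = self._fit_at(X, y, self.threshold_)
        return self

    def predict_scores(self, X):
        return self._score_with(self.params_, np.asarray(X, float))

    def importance(self, feature_names: Sequence[str]) -> pd.DataFrame:
        """|shrunken difference| of the surviving features, descending."""
        imp = np.abs(self.params_["d_shrunk"][1])
        df = pd.DataFrame({"predictor": list(feature_names), "importance": imp})
        df = df[df["importance"] > 0].sort_values(
            "importance", ascending=False, kind="stable")
        return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# k-nearest neighbours
# ---------------------------------------------------------------------------

class KNearestNeighbors:
    """Standardized k-NN; the score is the positive-class vote fraction."""

    name = "knn"

    def __init__(self, k: int | None = None, k_grid: Sequence[int] = KNN_GRID,
                 n_inner: int = 5):
        self.k = k
        self.k_grid = list(k_grid)
        self.n_inner = n_inner

    def _scores_at(self, Xtr, ytr, Xte, k):
        d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
        nbr = np.argsort(d2, axis=1, kind="stable")[:, :k]
        return ytr[nbr].mean(axis=1)

    def fit(self, X, y, rng=None):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mean_) / self.sd_
        if self.k is None:
            rng = rng if rng is not None else np.random.default_rng(0)
            grid = [k for k in self.k_grid if k <= int(0.8 * len(y))]
            if not grid:
                raise ValueError("k grid exceeds training size")
            acc = {k: [] for k in grid}
            for _ in range(self.n_inner):
                tr, te = _stratified_split(y, 0.8, rng)
                for k in grid:
                    pred = (self._scores_at(Z[tr], y[tr], Z[te], k) >= 0.5).astype(int)
                    acc[k].append(np.mean(pred == y[te]))
            self.k_ = _inner_tune(acc, grid, prefer_larger=False)
        else:
            if self.k > len(y):
                raise ValueError("k cannot exceed the training size")
            self.k_ = self.k
        self.Ztr_, self.ytr_ = Z, y
        return self

    def predict_scores(self, X):
        Z = (np.asarray(X, float) - self.mean_) / self.sd_
        return self._scores_at(self.Ztr_, self.ytr_, Z, self.k_)


# ---------------------------------------------------------------------------
# Naive Bayes (Gaussian or kernel-density class conditionals)
# ---------------------------------------------------------------------------

class NaiveBayes:
    """Independent-feature Bayes classifier with log-space accumulation.

    ``kernel=False`` models each class conditional as Gaussian;
    ``kernel=True`` uses a Gaussian kernel density per feature (Silverman
    bandwidth scaled by ``bandwidth_factor``). As the bandwidth grows the
    class likelihoods flatten and the posterior tends to the priors.
    """

    name = "nb"

    def __init__(self, kernel: bool = False, bandwidth_factor: float = 1.0,
                 var_floor: float = 1e-9):
        self.kernel = kernel
        self.bandwidth_factor = bandwidth_factor
        self.var_floor = var_floor

    def fit(self, X, y, rng=None):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.array([0, 1])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        if self.kernel:
            self.train_ = [X[y == c] for c in self.classes_]
            # one bandwidth per feature, shared by both classes, so an
            # arbitrarily wide kernel flattens the likelihood ratio to 1
            sd = np.maximum(X.std(axis=0, ddof=1), np.sqrt(self.var_floor))
            bw = self.bandwidth_factor * 1.06 * sd * max(len(X), 2) ** (-1 / 5)
            self.bw_ = [bw, bw]
        else:
            self.mu_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
            self.var_ = np.vstack([
                np.maximum(X[y == c].var(axis=0, ddof=1), self.var_floor)
                for c in self.classes_
            ])
        return self

    def _log_lik(self, X, k):
        if self.kernel:
            xc, bw = self.train_[k], self.bw_[k]
            # log mean of Gaussian kernels, feature by feature
            z = (X[:, None, :] - xc[None, :, :]) / bw[None, None, :]
            logk = -0.5 * z ** 2 - np.log(bw)[None, None, :] - 0.5 * np.log(2 * np.pi)
            m = logk.max(axis=1)
            log_dens = m + np.log(np.exp(logk - m[:, None, :]).mean(axis=1))
            return log_dens.sum(axis=1)
        mu, var = self.mu_[k], self.var_[k]
        return (-0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var)).sum(axis=1)

    def predict_scores(self, X):
        X = np.asarray(X, float)
        logp = np.vstack([
            self._log_lik(X, k) + np.log(self.priors_[k]) for k in range(2)
        ]).T
        m = logp.max(axis=1, keepdims=True)
        post = np.exp(logp - m)
        return post[:, 1] / post.sum(axis=1)


class SklearnAdapter:
    """Wrap any scikit-learn style estimator into the fit/score contract."""

    def __init__(self, estimator, name: str | None = None):
        self.estimator = estimator
        self.name = name or type(estimator).__name__.lower()

    def fit(self, X, y, rng=None):
        import sklearn.base
        self.model_ = sklearn.base.clone(self.estimator)
        if rng is not None and "random_state" in self.model_.get_params():
            self.model_.set_params(random_state=int(rng.integers(2 ** 31 - 1)))
        self.model_.fit(X, y)
        return self

    def predict_scores(self, X):
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(X)[:, 1]
        raw = self.model_.decision_function(X)
        return 1.0 / (1.0 + np.exp(-raw))


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass
class ResamplingResult:
    """Averaged held-out performance of one model over stratified splits."""

    model: str
    predictor_set: str
    sensitivity: float
    specificity: float
    youden: float
    auc: float
    n_splits: int
    n_failed: int
    per_split: pd.DataFrame = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "model": self.model, "predictor_set": self.predictor_set,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "youden": self.youden, "auc": self.auc,
            "n_splits": self.n_splits, "n_failed": self.n_failed,
        }


def assemble_predictors(table: CohortTable, values: pd.DataFrame,
                        predictors: Sequence[str]) -> pd.DataFrame:
    """Marker columns plus the always-included age, gender, APOE e4 status."""
    X = values[list(predictors)].copy()
    X["age_at_lp"] = table.demographics["age_at_lp"].to_numpy(float)
    X["female"] = table.female_indicator().to_numpy(float)
    X["apoe4"] = table.e4_carrier().to_numpy(float)
    return X


def resample_evaluate(classifier: Classifier, X: pd.DataFrame, labels: np.ndarray,
                      n_splits: int = 200, train_frac: float = 0.80,
                      seed: int = 0, predictor_set: str = "",
                      ) -> ResamplingResult:
    """Average a classifier's held-out performance over stratified splits.

    Each split refits (and, per the classifier, retunes) on the training
    80% only; test-set sensitivity and specificity are taken at the 0.5
    score cut, the AUC from the held-out scores. A split on which the
    classifier raises is logged, excluded, and counted.
    """
    Xa = X.to_numpy(float)
    y = np.asarray(labels).astype(int)
    obs = ~np.isnan(Xa).any(axis=1)
    Xa, y = Xa[obs], y[obs]
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for split in range(n_splits):
        tr, te = _stratified_split(y, train_frac, rng)
        try:
            classifier.fit(Xa[tr], y[tr], rng)
            scores = np.asarray(classifier.predict_scores(Xa[te]), float)
        except Exception as exc:  # noqa: BLE001 - adapter models may fail per split
            n_failed += 1
            logger.warning("split %d failed for %s: %s", split, classifier.name, exc)
            continue
        pred = (scores >= 0.5).astype(int)
        yt = y[te]
        sens = float(np.mean(pred[yt == 1] == 1))
        spec = float(np.mean(pred[yt == 0] == 0))
        rows.append({
            "split": split, "sensitivity": sens, "specificity": spec,
            "youden": youden_index(sens, spec),
            "auc": empirical_auc(scores, yt),
        })
    per_split = pd.DataFrame(rows)
    if per_split.empty:
        raise RuntimeError(f"classifier {classifier.name} failed on every split")
    mean = per_split.mean(numeric_only=True)
    return ResamplingResult(
        model=classifier.name, predictor_set=predictor_set,
        sensitivity=float(mean["sensitivity"]), specificity=float(mean["specificity"]),
        youden=youden_index(float(mean["sensitivity"]), float(mean["specificity"])),
        auc=float(mean["auc"]), n_splits=len(per_split), n_failed=n_failed,
        per_split=per_split,
    )


# ---------------------------------------------------------------------------
# Importance overlap
# ---------------------------------------------------------------------------

@dataclass
class ImportanceRanking:
    model: str
    ranking: pd.DataFrame  # columns predictor, importance; sorted descending

    def top(self, k: int) -> set[str]:
        if k > len(self.ranking):
            raise ValueError(f"k={k} exceeds ranking length {len(self.ranking)}")
        return set(self.ranking["predictor"].iloc[:k])


def importance_overlap(rankings: Sequence[ImportanceRanking], k: int = 15,
                       reference_set: Sequence[str] | None = None) -> dict:
    """Pairwise and global intersections of top-k predictor sets.

    ``reference_set`` (e.g. the ROC-stage panel marker list) adds a
    per-model intersection count with that external list.
    """
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings")
    tops = {r.model: r.top(k) for r in rankings}
    models = list(tops)
    pairwise = {
        f"{a}|{b}": len(tops[a] & tops[b])
        for i, a in enumerate(models) for b in models[i + 1:]
    }
    global_set = set.intersection(*tops.values())
    out = {
        "k": k,
        "pairwise": pairwise,
        "global_intersection": sorted(global_set),
        "global_count": len(global_set),
    }
    if reference_set is not None:
        ref = set(reference_set)
        out["reference_overlap"] = {m: len(tops[m] & ref) for m in models}
    return out
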