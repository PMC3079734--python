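"""Binormal optimal-linear-combination ROC machinery with bootstrap panel
evaluation.

Under the binormal model a marker panel is multivariate Gaussian within
each diagnostic class, with class moments (mu0, Sigma0) and (mu1, Sigma1).
The linear combination maximizing the area under the ROC curve has
coefficients a proportional to (Sigma0 + Sigma1)^-1 (mu1 - mu0), and the
optimal AUC has the closed form

    AUC = Phi( sqrt( (mu1-mu0)' (Sigma0+Sigma1)^-1 (mu1-mu0) ) ).

Sensitivity at a fixed specificity follows from the Gaussian class-score
distributions. Panels are evaluated by a stratified bootstrap: on each
resample the binormal model is refit, AUC and sensitivity at the target
specificity are recorded, and the gain of the full panel over its nested
reduced panel is tested on the resampled combination scores; means, SDs
and 95% CIs over the B iterations summarize expected future performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

logger = logging.getLogger("csfpanels")


# ---------------------------------------------------------------------------
# Empirical AUC
# ---------------------------------------------------------------------------

def empirical_auc(scores: np.ndarray, labels: np.ndarray,
                  orient: bool = False) -> float:
    """Mann-Whitney AUC estimate with ties counted 1/2.

    By default the raw orientation is returned (probability a positive
    outscores a negative), which may fall below 0.5; ``orient=True``
    returns max(AUC, 1-AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(max(auc, 1 - auc)) if orient else float(auc)


def empirical_sensitivity_at_specificity(scores: np.ndarray, labels: np.ndarray,
                                         specificity: float = 0.80) -> float:
    """Sensitivity read off the interpolated empirical ROC curve."""
    if not 0 < specificity < 1:
        raise ValueError("specificity must lie in (0,1)")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.interp(1 - specificity, fpr, tpr))


# ---------------------------------------------------------------------------
# Binormal model
# ---------------------------------------------------------------------------

@dataclass
class BinormalModel:
    """Per-class Gaussian moments of a panel plus its optimal combination."""

    markers: list[str]
    mu0: np.ndarray
    mu1: np.ndarray
    sigma0: np.ndarray
    sigma1: np.ndarray
    a: np.ndarray       # unit-norm coefficients, oriented so a'(mu1-mu0) >= 0
    auc: float          # analytic optimal AUC, in [0.5, 1]

    @property
    def delta(self) -> np.ndarray:
        return self.mu1 - self.mu0

    def combination_scores(self, values: np.ndarray) -> np.ndarray:
        """Project subject rows onto the combination direction."""
        return np.asarray(values, dtype=float) @ self.a


def fit_binormal(values: pd.DataFrame | np.ndarray, panel: Sequence[str] | None,
                 labels: np.ndarray, ridge: float = 0.0,
                 strict: bool = False) -> BinormalModel:
    """Estimate class moments for a panel and solve for its optimal combination.

    ``values`` holds analysis-scale marker columns; ``labels`` is the binary
    class (1 = impaired). Group means and unbiased covariances are the
    estimates. A singular moment sum is ridge-regularized (logged) unless
    ``strict`` is set, in which case it raises.
    """
    if isinstance(values, pd.DataFrame):
        X = values[list(panel)].to_numpy(float) if panel is not None else values.to_numpy(float)
        names = list(panel) if panel is not None else list(values.columns)
    else:
        X = np.asarray(values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(panel) if panel is not None else [f"m{j}" for j in range(X.shape[1])]
    labels = np.asarray(labels).astype(int)
    obs = ~np.isnan(X).any(axis=1)
    X, labels = X[obs], labels[obs]
    p = X.shape[1]
    x0, x1 = X[labels == 0], X[labels == 1]
    if len(x0) < p + 1 or len(x1) < p + 1:
        raise ValueError("each class needs at least panel size + 1 subjects")
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    s0 = np.cov(x0, rowvar=False, ddof=1).reshape(p, p)
    s1 = np.cov(x1, rowvar=False, ddof=1).reshape(p, p)
    try:
        a, auc = optimal_combination(mu0, mu1, s0, s1)
    except np.linalg.LinAlgError:
        if strict or ridge <= 0:
            raise np.linalg.LinAlgError(
                "singular Sigma0+Sigma1; pass ridge=<epsilon> to regularize")
        logger.warning("ridge-regularizing singular moment sum (epsilon=%g)", ridge)
        eye = np.eye(p)
        a, auc = optimal_combination(mu0, mu1, s0 + ridge * eye, s1 + ridge * eye)
    return BinormalModel(names, mu0, mu1, s0, s1, a, auc)


def optimal_combination(mu0: np.ndarray, mu1: np.ndarray,
                        sigma0: np.ndarray, sigma1: np.ndarray,
                        ) -> tuple[np.ndarray, float]:
    """Closed-form AUC-optimal coefficients and their analytic AUC.

    a is proportional to (Sigma0+Sigma1)^-1 (mu1-mu0), normalized to unit
    length with the sign that makes a'(mu1-mu0) >= 0 (so AUC >= 0.5); a
    single marker reduces to AUC = Phi(|delta| / sqrt(s0^2 + s1^2)).
    """
    mu0, mu1 = np.atleast_1d(np.asarray(mu0, float)), np.atleast_1d(np.asarray(mu1, float))
    sigma0 = np.atleast_2d(np.asarray(sigma0, float))
    sigma1 = np.atleast_2d(np.asarray(sigma1, float))
    delta = mu1 - mu0
    s = sigma0 + sigma1
    cond = np.linalg.cond(s)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("Sigma0+Sigma1 is singular or near-singular")
    a = np.linalg.solve(s, delta)
    norm_a = np.linalg.norm(a)
    if norm_a == 0:
        a = np.zeros_like(delta)
        a[0] = 1.0  # degenerate zero-separation panel: any direction, AUC 0.5
        return a, 0.5
    a = a / norm_a
    if a @ delta < 0:
        a = -a
    auc = float(norm.cdf(np.sqrt(delta @ np.linalg.solve(s, delta))))
    return a, auc


def direction_auc(model: BinormalModel, u: np.ndarray) -> float:
    """Analytic AUC of an arbitrary combination direction under the model."""
    u = np.asarray(u, dtype=float)
    denom = np.sqrt(u @ (model.sigma0 + model.sigma1) @ u)
    if denom == 0:
        return 0.5
    return float(norm.cdf((u @ model.delta) / denom))


def sensitivity_at_specificity(model: BinormalModel,
                               specificity: float = 0.80) -> float:
    """Binormal sensitivity of the optimal combination at a fixed specificity.

    The threshold is c = a'mu0 + z_spec sqrt(a'Sigma0 a); sensitivity is
    Phi((a'mu1 - c) / sqrt(a'Sigma1 a)). Identical classes give the
    diagonal ROC, i.e. sensitivity = 1 - specificity.
    """
    if not 0 < specificity < 1:
        raise ValueError("specificity must lie in (0,1)")
    a = model.a
    sd0 = np.sqrt(a @ model.sigma0 @ a)
    sd1 = np.sqrt(a @ model.sigma1 @ a)
    c = a @ model.mu0 + norm.ppf(specificity) * sd0
    if sd1 == 0:
        return float(a @ model.mu1 > c)
    return float(norm.cdf((a @ model.mu1 - c) / sd1))


# ---------------------------------------------------------------------------
# Panel expansion
# ---------------------------------------------------------------------------

def expand_panels(ranked_2marker_panels: Sequence[Sequence[str]],
                  ranked_single_markers: Sequence[str],
                  n_base: int = 4, n_candidates: int = 10,
                  ) -> list[tuple[str, ...]]:
    """Cartesian expansion of top 2-marker panels with top single markers.

    A candidate already inside a base panel is skipped; ordering is
    deterministic by (base rank, candidate rank). If fewer bases or
    candidates exist than requested, the available ones are used (with a
    warning).
    """
    bases = [tuple(p) for p in ranked_2marker_panels[:n_base]]
    cands = list(ranked_single_markers[:n_candidates])
    if len(bases) < n_base or len(cands) < n_candidates:
        logger.warning("expansion requested %dx%d but only %dx%d available",
                       n_base, n_candidates, len(bases), len(cands))
    out: list[tuple[str, ...]] = []
    seen = set()
    for base in bases:
        for cand in cands:
            if cand in base:
                continue
            panel = base + (cand,)
            key = frozenset(panel)
            if key not in seen:
                seen.add(key)
                out.append(panel)
    return out


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

def _delong_p_gain(s_full: np.ndarray, s_red: np.ndarray,
                   labels: np.ndarray) -> float:
    """One-sided p-value that the full panel's AUC exceeds the reduced one's,
    from the paired normal approximation on shared subjects (DeLong-type
    placement-value covariance)."""
    labels = np.asarray(labels).astype(int)
    pos, neg = labels == 1, labels == 0
    m, n = int(pos.sum()), int(neg.sum())

    def placements(s):
        # V10[i]: fraction of negatives the i-th positive outscores (ties 1/2)
        sp, sn = s[pos], s[neg]
        v10 = (np.sum(sp[:, None] > sn[None, :], axis=1)
               + 0.5 * np.sum(sp[:, None] == sn[None, :], axis=1)) / n
        v01 = (np.sum(sp[None, :] > sn[:, None], axis=1)
               + 0.5 * np.sum(sp[None, :] == sn[:, None], axis=1)) / m
        return v10, v01

    v10f, v01f = placements(np.asarray(s_full, float))
    v10r, v01r = placements(np.asarray(s_red, float))
    auc_f, auc_r = v10f.mean(), v10r.mean()
    d = auc_f - auc_r
    s10 = np.cov(np.vstack([v10f, v10r]), ddof=1)
    s01 = np.cov(np.vstack([v01f, v01r]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0 if d <= 0 else 0.0
    return float(norm.sf(d / np.sqrt(var)))


@dataclass
class PanelEvaluation:
    """Bootstrap-averaged performance of a panel against its nested reduction."""

    panel: tuple[str, ...]
    reduced_panel: tuple[str, ...]
    B: int
    auc_mean: float
    auc_sd: float
    auc_ci: tuple[float, float]
    sens_mean: float
    sens_sd: float
    sens_ci: tuple[float, float]
    p_mean: float
    p_sd: float
    p_ci: tuple[float, float]
    n_redrawn: int = 0

    def as_row(self) -> dict:
        return {
            "panel": " + ".join(self.panel),
            "reduced_panel": " + ".join(self.reduced_panel),
            "auc": self.auc_mean, "auc_sd": self.auc_sd,
            "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1],
            "sensitivity": self.sens_mean, "sensitivity_sd": self.sens_sd,
            "sens_ci_low": self.sens_ci[0], "sens_ci_high": self.sens_ci[1],
            "p_value": self.p_mean, "p_sd": self.p_sd,
            "p_ci_low": self.p_ci[0], "p_ci_high": self.p_ci[1],
            "B": self.B,
        }


def _summary(x: np.ndarray, B: int) -> tuple[float, float, tuple[float, float]]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if B > 1 else 0.0
    half = 1.959963984540054 * sd / np.sqrt(B)
    return mean, sd, (mean - half, mean + half)


def bootstrap_evaluate(values: pd.DataFrame, labels: np.ndarray,
                       panel: Sequence[str], reduced_panel: Sequence[str],
                       B: int = 100, specificity: float = 0.80,
                       seed: int = 0, max_redraws: int = 100,
                       ) -> PanelEvaluation:
    """Stratified bootstrap evaluation of a nested panel pair.

    Each of the B resamples draws subjects with replacement within class,
    keeping the original class sizes; both panels are refit on the
    resample, and the analytic AUC, the binormal sensitivity at the target
    specificity, and the one-sided p-value for the AUC gain of the full
    panel are recorded. Resamples on which a binormal fit degenerates are
    redrawn (counted). The identical-panel case is degenerate by
    definition: its p-value is 1.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    panel, reduced_panel = tuple(panel), tuple(reduced_panel)
    if not set(reduced_panel) <= set(panel):
        raise ValueError("reduced_panel must be nested inside panel")
    same = set(reduced_panel) == set(panel)
    labels = np.asarray(labels).astype(int)
    X = values[list(panel)].to_numpy(float)
    obs = ~np.isnan(X).any(axis=1)
    X, labels = X[obs], labels[obs]
    idx_pos = np.nonzero(labels == 1)[0]
    idx_neg = np.nonzero(labels == 0)[0]
    col = {m: j for j, m in enumerate(panel)}
    red_cols = [col[m] for m in reduced_panel]

    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    sens = np.empty(B)
    pvals = np.empty(B)
    n_redrawn = 0
    b = 0
    while b < B:
        take = np.concatenate([rng.choice(idx_pos, len(idx_pos), replace=True),
                               rng.choice(idx_neg, len(idx_neg), replace=True)])
        Xb = X[take]
        yb = labels[take]
        try:
            full = fit_binormal(Xb, None, yb)
            red = fit_binormal(Xb[:, red_cols], None, yb)
        except (np.linalg.LinAlgError, ValueError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            logger.debug("degenerate resample redrawn (%d so far)", n_redrawn)
            continue
        aucs[b] = full.auc
        sens[b] = sensitivity_at_specificity(full, specificity)
        if same:
            pvals[b] = 1.0
        else:
            pvals[b] = _delong_p_gain(full.combination_scores(Xb),
                                      red.combination_scores(Xb[:, red_cols]),
                                      yb)
        b += 1

    auc_mean, auc_sd, auc_ci = _summary(aucs, B)
    s_mean, s_sd, s_ci = _summary(sens, B)
    p_mean, p_sd, p_ci = _summary(pvals, B)
    return PanelEvaluation(panel, reduced_panel, B,
                           auc_mean, auc_sd, auc_ci,
                           s_mean, s_sd, s_ci,
                           p_mean, p_sd, p_ci, n_redrawn)


def rank_markers_by_auc(values: pd.DataFrame, labels: np.ndarray,
                        markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Single-marker analytic AUCs, sorted descending (panel-building input)."""
    markers = list(markers) if markers is not None else list(values.columns)
    rows = []
    for m in markers:
        model = fit_binormal(values, [m], labels)
        rows.append({"marker": m, "auc": model.auc})
    return pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
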