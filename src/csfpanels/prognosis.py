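"""Time-to-conversion analysis: Z-scoring, Cox proportional-hazards
fitting, staged variable selection, and the overall panel hazard ratio.

Baseline markers of cognitively normal (CDR 0) subjects are Z-scored so
hazard ratios are comparable per SD; age stays in raw years so its HR is
per year. Candidate markers pass a univariate screen (p < 0.15), strongly
correlated survivors (Spearman |rho| >= 0.4, p < 0.05) are never
co-included but spawn alternative candidate models, multivariate models
are pruned backward at p < 0.05 (age and gender re-tested at every step),
and the final models are ranked by AIC. The overall panel HR is the
product of the component hazard ratios, i.e. exp of the coefficient sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .cohort import FollowUpRecord

logger = logging.getLogger("csfpanels")


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1. Constant input is an error."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    sd = np.std(x[obs], ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot Z-score a constant vector")
    return (x - np.mean(x[obs])) / sd


def reciprocal_marker(values: np.ndarray) -> np.ndarray:
    """1/value, computed before any log or Z transform.

    Used for markers whose *low* levels raise risk (e.g. amyloid-beta 42),
    so the reciprocal's hazard ratio comes out above 1.
    """
    x = np.asarray(values, dtype=float)
    if (x == 0).any():
        raise ValueError("reciprocal undefined at zero")
    return 1.0 / x


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxModelResult:
    """One fitted Cox model: per-covariate effects plus fit summaries."""

    covariates: list[str]
    beta: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    log_likelihood: float
    aic: float
    n: int
    n_events: int

    @property
    def overall_hr(self) -> float:
        return overall_hr(self)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta, "hr": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        })


def cox_fit(records: Sequence[FollowUpRecord],
            covariates: pd.DataFrame) -> CoxModelResult:
    """Fit a Cox proportional-hazards model by partial likelihood.

    ``covariates`` is indexed by subject_id and is aligned to the records;
    tied event times are handled by the Efron approximation, confidence
    intervals and p-values are Wald-based, and AIC is
    -2 log(partial likelihood) + 2 (number of covariates).
    """
    ids = [r.subject_id for r in records]
    missing = [i for i in ids if i not in covariates.index]
    if missing:
        raise ValueError(f"covariates missing for subjects: {missing[:5]}")
    df = covariates.loc[ids].copy()
    df["_time"] = [r.time_to_event for r in records]
    df["_event"] = [int(r.event) for r in records]
    df = df.dropna()
    if df["_event"].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-9, "max_steps": 500})
    except ConvergenceError as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    names = list(s.index)
    return CoxModelResult(
        covariates=names,
        beta=s["coef"].rename(None),
        hr=s["exp(coef)"].rename(None),
        ci_low=s["exp(coef) lower 95%"].rename(None),
        ci_high=s["exp(coef) upper 95%"].rename(None),
        p=s["p"].rename(None),
        log_likelihood=float(cph.log_likelihood_),
        aic=float(-2 * cph.log_likelihood_ + 2 * len(names)),
        n=int(len(df)),
        n_events=int(df["_event"].sum()),
    )


def overall_hr(model: "CoxModelResult | Iterable[float]") -> float:
    """Overall panel hazard ratio: the product of component HRs,
    reported to 3 decimals (equivalently exp of the coefficient sum)."""
    hrs = model.hr if isinstance(model, CoxModelResult) else list(model)
    return round(float(np.prod(np.asarray(hrs, dtype=float))), 3)


# ---------------------------------------------------------------------------
# Staged panel selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Audit trail of the staged selection."""

    univariate: pd.DataFrame                       # marker, hr, p, kept
    conflicts: list[dict] = field(default_factory=list)  # pair, rho, p
    candidate_sets: list[tuple[str, ...]] = field(default_factory=list)
    drops: list[dict] = field(default_factory=list)      # per-model drop records
    note: str = ""


def _maximal_conflict_free_sets(markers: list[str],
                                conflicts: set[frozenset]) -> list[tuple[str, ...]]:
    """All maximal subsets containing no conflicting pair (order-preserving).

    Exhaustive for up to 16 markers; beyond that, conflicted markers are
    resolved greedily one edge at a time (each endpoint spawning a branch).
    """
    if not conflicts:
        return [tuple(markers)]
    if len(markers) <= 16:
        from itertools import combinations
        valid = []
        for r in range(len(markers), 0, -1):
            for comb in combinations(markers, r):
                if any(frozenset(pair) in conflicts
                       for pair in combinations(comb, 2)):
                    continue
                key = set(comb)
                if not any(key < set(v) for v in valid):
                    valid.append(comb)
        return valid
    # greedy branching fallback for large marker sets
    out: list[tuple[str, ...]] = []
    stack = [tuple(markers)]
    seen = set()
    while stack:
        cur = stack.pop()
        from itertools import combinations
        bad = next((pair for pair in combinations(cur, 2)
                    if frozenset(pair) in conflicts), None)
        if bad is None:
            if frozenset(cur) not in seen:
                seen.add(frozenset(cur))
                out.append(cur)
            continue
        for drop in bad:
            stack.append(tuple(m for m in cur if m != drop))
    return out


def select_prognostic_panel(marker_values: pd.DataFrame,
                            records: Sequence[FollowUpRecord],
                            candidate_markers: Sequence[str],
                            demographics: pd.DataFrame,
                            screen_alpha: float = 0.15,
                            retention_alpha: float = 0.05,
                            corr_threshold: float = 0.40,
                            ) -> tuple[list[CoxModelResult], SelectionTrace]:
    """Staged Cox model selection over candidate prognostic markers.

    ``marker_values`` holds analysis-scale marker columns for the CDR 0
    follow-up subjects (indexed by subject_id); markers are Z-scored over
    this analysis set. ``demographics`` supplies ``age_at_lp`` (raw
    years), ``female`` and ``apoe4`` columns, which are always entered and
    re-tested but dropped when nonsignificant.

    Stages: (1) univariate screen at ``screen_alpha``; (2) survivors with
    Spearman |rho| >= ``corr_threshold`` (p < 0.05) are split across
    alternative candidate models, never co-included; (3) each candidate
    model is pruned backward, one worst covariate at a time, until every
    remaining covariate has p < ``retention_alpha``; (4) final models are
    sorted by AIC (lowest first) with the overall panel HR attached.
    """
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    candidate_markers = list(candidate_markers)
    z = pd.DataFrame(
        {m: zscore(marker_values[m].to_numpy(float)) for m in candidate_markers},
        index=marker_values.index,
    )
    demo = demographics[["age_at_lp", "female", "apoe4"]]

    # stage 1: univariate screen
    uni_rows = []
    kept: list[str] = []
    for m in candidate_markers:
        try:
            res = cox_fit(records, z[[m]])
        except (ConvergenceError, ValueError) as exc:
            logger.warning("univariate Cox failed for %s: %s", m, exc)
            uni_rows.append({"marker": m, "hr": np.nan, "p": np.nan, "kept": False})
            continue
        p = float(res.p.iloc[0])
        keep = p < screen_alpha
        uni_rows.append({"marker": m, "hr": float(res.hr.iloc[0]), "p": p, "kept": keep})
        if keep:
            kept.append(m)
    trace = SelectionTrace(univariate=pd.DataFrame(uni_rows).set_index("marker"))

    if not kept:
        trace.note = "no marker passed the univariate screen; covariate-only model"
        base = cox_fit(records, demo)
        return [base], trace

    # stage 2: correlated-pair arbitration
    conflicts: set[frozenset] = set()
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            obs = ~np.isnan(z[a]) & ~np.isnan(z[b])
            rho, p = stats.spearmanr(z.loc[obs, a], z.loc[obs, b])
            if abs(rho) >= corr_threshold and p < 0.05:
                conflicts.add(frozenset((a, b)))
                trace.conflicts.append({"pair": (a, b), "rho": float(rho),
                                        "p": float(p)})
    trace.candidate_sets = _maximal_conflict_free_sets(kept, conflicts)

    # stage 3: backward pruning per candidate set
    models: list[CoxModelResult] = []
    for cand in trace.candidate_sets:
        cols = list(cand) + ["age_at_lp", "female", "apoe4"]
        X = pd.concat([z[list(cand)], demo], axis=1)[cols]
        while True:
            model = cox_fit(records, X[cols])
            worst = model.p.idxmax()
            if model.p.max() < retention_alpha or len(cols) == 1:
                break
            trace.drops.append({"candidate_set": cand, "dropped": worst,
                                "p": float(model.p.max())})
            cols.remove(worst)
        models.append(model)

    # stage 4: AIC ranking
    models.sort(key=lambda m: m.aic)
    return models, trace
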