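"""End-to-end orchestration: simulate -> qc -> screen -> panels -> ml ->
prognosis, with all stage outputs written through one report call.

Stage seeds are spawned deterministically from the run seed, so a fixed
configuration yields byte-identical result tables across executions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ml as ml_mod
from . import prognosis as prog_mod
from . import qc as qc_mod
from . import roc as roc_mod
from . import screen as screen_mod
from .cohort import CohortTable, RunConfig, write_report
from .simulate import SimScenario, generate_cohort, generate_survival

logger = logging.getLogger("csfpanels")


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig,
                 scenario: SimScenario | None = None,
                 out_dir: str | Path | None = None,
                 n_base: int = 4, n_candidates: int = 10,
                 ml_models: tuple[str, ...] = ("nsc", "knn", "nb"),
                 n_ml_markers: int = 10,
                 survival_betas: dict[str, float] | None = None,
                 baseline_hazard: float = 0.03,
                 ) -> dict:
    """Run every stage on a synthetic cohort and write the report tables.

    Returns a dict of in-memory results keyed by stage name. ``out_dir``
    defaults to ``config.out_dir``; panel expansion and predictor-set
    sizes are exposed so test runs can scale the problem down.
    """
    scenario = scenario if scenario is not None else SimScenario()
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    s_sim, s_surv, s_boot, s_ml, s_extra, _ = _stage_seeds(config.seed)

    # --- simulate ---------------------------------------------------------
    cohort, truth = generate_cohort(scenario, s_sim)
    if survival_betas is None:
        sig = truth.signal_analytes[:2]
        survival_betas = {m: 0.5 for m in sig}
        survival_betas["age"] = 0.09
    records, _ = generate_survival(cohort, survival_betas, baseline_hazard,
                                   seed=s_surv, truth=truth)

    # --- qc ---------------------------------------------------------------
    clean, qc_report, specs = qc_mod.run_qc(
        cohort, config.missing_threshold, config.outlier_z, config.knn_k)
    analysis = qc_mod.apply_transforms(clean, specs)

    # --- screen -----------------------------------------------------------
    screen_tab = screen_mod.ancova_screen(
        clean, specs, config.bonferroni_alpha, config.bonferroni_n)
    ref = pd.DataFrame({"age": clean.demographics["age_at_lp"].to_numpy(float)},
                       index=analysis.index)
    corr_tab = screen_mod.spearman_screen(clean, ref)

    # --- roc panels -------------------------------------------------------
    labels = clean.impaired().to_numpy()
    sig_markers = list(screen_tab.index[screen_tab["p"] < 0.05])
    if len(sig_markers) < 3:
        sig_markers = list(screen_tab.index[: max(3, n_candidates)])
    singles = roc_mod.rank_markers_by_auc(analysis, labels, sig_markers)
    top = list(singles["marker"])
    base_anchor = top[0]
    pair_rows = []
    for m in top[1:]:
        model = roc_mod.fit_binormal(analysis, [base_anchor, m], labels)
        pair_rows.append({"panel": (base_anchor, m), "auc": model.auc})
    pairs = pd.DataFrame(pair_rows).sort_values("auc", ascending=False)
    bases = [tuple(p) for p in pairs["panel"].iloc[:n_base]]
    panels = roc_mod.expand_panels(bases, top, n_base, n_candidates)
    evals = []
    for i, panel in enumerate(panels):
        ev = roc_mod.bootstrap_evaluate(
            analysis, labels, panel, panel[:2], config.bootstrap_B,
            config.specificity_target, seed=s_boot + i)
        evals.append(ev)
    panel_tab = pd.DataFrame([e.as_row() for e in evals])

    # --- ml ---------------------------------------------------------------
    classifiers = {
        "nsc": ml_mod.NearestShrunkenCentroids,
        "knn": ml_mod.KNearestNeighbors,
        "nb": ml_mod.NaiveBayes,
    }
    marker_sets = {
        "panel": top[: min(3, len(top))],
        "panel+rbm": top[: min(n_ml_markers, len(top))],
    }
    ml_rows = []
    rankings = []
    for set_name, markers in marker_sets.items():
        X = ml_mod.assemble_predictors(clean, analysis, markers)
        for name in ml_models:
            clf = classifiers[name]()
            res = ml_mod.resample_evaluate(
                clf, X, labels, config.n_splits, config.train_frac,
                seed=s_ml, predictor_set=set_name)
            ml_rows.append(res.as_row())
            if name == "nsc" and set_name == "panel+rbm":
                clf.fit(X.dropna().to_numpy(float),
                        labels[~X.isna().any(axis=1)],
                        np.random.default_rng(s_ml))
                rankings.append(ml_mod.ImportanceRanking(
                    "nsc", clf.importance(list(X.columns))))
    ml_tab = pd.DataFrame(ml_rows)

    # --- prognosis --------------------------------------------------------
    follow_ids = [r.subject_id for r in records]
    marker_values = analysis.loc[follow_ids]
    demo = pd.DataFrame({
        "age_at_lp": clean.demographics.loc[follow_ids, "age_at_lp"].to_numpy(float),
        "female": clean.female_indicator().loc[follow_ids].to_numpy(),
        "apoe4": clean.e4_carrier().loc[follow_ids].to_numpy(),
    }, index=pd.Index(follow_ids, name="subject_id"))
    candidates = [m for m in survival_betas if m != "age" and m in marker_values.columns]
    extra = [m for m in top[:5] if m not in candidates]
    cox_models, trace = prog_mod.select_prognostic_panel(
        marker_values, records, candidates + extra, demo,
        config.screen_alpha, config.retention_alpha, config.corr_threshold)
    cox_rows = []
    for rank, m in enumerate(cox_models):
        for cov in m.covariates:
            cox_rows.append({
                "model_rank": rank, "covariate": cov,
                "hr": m.hr[cov], "ci_low": m.ci_low[cov],
                "ci_high": m.ci_high[cov], "p": m.p[cov],
                "aic": m.aic, "overall_hr": m.overall_hr,
            })
    cox_tab = pd.DataFrame(cox_rows)

    tables = {
        "screen": screen_tab.reset_index(),
        "correlations": corr_tab.reset_index(),
        "panels": panel_tab,
        "ml": ml_tab,
        "cox": cox_tab,
    }
    write_report(tables, out_dir, config)
    return {
        "cohort": cohort, "truth": truth, "clean": clean, "qc": qc_report,
        "transforms": specs, "screen": screen_tab, "correlations": corr_tab,
        "panels": evals, "ml": ml_tab, "cox_models": cox_models,
        "trace": trace, "tables": tables,
    }
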