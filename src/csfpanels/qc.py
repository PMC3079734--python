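"""Data-cleaning rules: measurability filter, LDL/2 imputation, 5-SD
outlier imputation by nearest neighbours, and Box-Cox transform selection.

The pass order is part of the contract and is logged:

1. measurability filter — drop analytes with >10% of cells missing or
   below the lower detection limit (pooled, strictly-greater-than);
2. below-LDL imputation — censored cells set to LDL/2;
3. outlier imputation — cells more than 5 SD from the (trimmed) mean
   replaced by the mean of the k nearest subjects;
4. transform selection — Box-Cox maximum-likelihood lambda with a
   profile-likelihood CI decides between identity and log10.

All steps run on the raw concentration scale; transforms are applied by
downstream stages via the emitted :class:`TransformSpec` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

logger = logging.getLogger("csfpanels")


@dataclass
class QCReport:
    """Per-analyte QC fractions plus the exact list of touched cells."""

    per_analyte: pd.DataFrame  # index analyte; missing_frac, below_ldl_frac, retained
    below_ldl_cells: list[tuple[str, str]] = field(default_factory=list)
    outlier_cells: pd.DataFrame | None = None  # subject, analyte, original, imputed

    @property
    def retained(self) -> list[str]:
        return list(self.per_analyte.index[self.per_analyte["retained"]])


@dataclass
class TransformSpec:
    """Chosen per-analyte transform with the Box-Cox evidence behind it."""

    analyte: str
    transform: str          # "identity" | "log10"
    lam: float | None       # Box-Cox MLE, None when the fit was not attempted
    ci: tuple[float, float] | None
    rationale: str

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.transform == "log10":
            return np.log10(values)
        return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# 1. Measurability filter
# ---------------------------------------------------------------------------

def flag_measurable(table: CohortTable, threshold: float = 0.10) -> QCReport:
    """Flag analytes whose missing-or-below-LDL fraction exceeds ``threshold``.

    Missing and censored cells are pooled for the rule; an analyte is
    excluded only when the pooled fraction is *strictly* greater than the
    threshold, so exactly 10.0% is still measurable.
    """
    n = table.n_subjects
    below = table.below_ldl.to_numpy()
    missing = np.isnan(table.values.to_numpy()) & ~below
    missing_frac = missing.sum(axis=0) / n
    below_frac = below.sum(axis=0) / n
    retained = (missing_frac + below_frac) <= threshold
    report = QCReport(
        per_analyte=pd.DataFrame(
            {
                "missing_frac": missing_frac,
                "below_ldl_frac": below_frac,
                "retained": retained,
            },
            index=table.values.columns.rename("analyte"),
        )
    )
    logger.info("measurability filter: %d of %d analytes retained (threshold %.0f%%)",
                retained.sum(), table.n_analytes, 100 * threshold)
    return report


# ---------------------------------------------------------------------------
# 2. Below-LDL imputation
# ---------------------------------------------------------------------------

def impute_below_ldl(values: np.ndarray, ldl: float,
                     below_ldl: np.ndarray | None = None) -> np.ndarray:
    """Set below-LDL cells of one analyte's value vector to LDL/2.

    Cells are treated as censored when flagged in ``below_ldl`` or when
    their observed value lies strictly below the LDL; all other cells are
    returned unchanged.
    """
    if ldl <= 0:
        raise ValueError("ldl must be positive")
    values = np.asarray(values, dtype=float).copy()
    censored = values < ldl
    if below_ldl is not None:
        censored = censored | np.asarray(below_ldl, dtype=bool)
    values[censored] = ldl / 2.0
    return values


def impute_below_ldl_table(table: CohortTable) -> tuple[CohortTable, list[tuple[str, str]]]:
    """Apply LDL/2 imputation to every analyte; return table + imputed cells."""
    out = table.copy()
    cells: list[tuple[str, str]] = []
    for name in out.analytes:
        mask = out.below_ldl[name].to_numpy()
        if mask.any():
            ldl = float(out.analyte_meta.loc[name, "ldl"])
            vals = out.values[name].to_numpy(float)
            vals[mask] = ldl / 2.0
            out.values[name] = vals
            cells.extend((sid, name) for sid in out.values.index[mask])
    return out, cells


# ---------------------------------------------------------------------------
# 3. Outlier detection and nearest-neighbour imputation
# ---------------------------------------------------------------------------

def _trimmed_moments(x: np.ndarray, z_cutoff: float) -> tuple[float, float]:
    """Mean/SD after one pass of trimming provisional >z outliers."""
    m, s = np.mean(x), np.std(x, ddof=1)
    if s == 0:
        return m, s
    keep = np.abs(x - m) <= z_cutoff * s
    if keep.sum() < 2:
        return m, s
    return float(np.mean(x[keep])), float(np.std(x[keep], ddof=1))


def detect_outliers(values: pd.DataFrame, z_cutoff: float = 5.0) -> pd.DataFrame:
    """Boolean mask of cells more than ``z_cutoff`` SD beyond the mean.

    The reference mean/SD per analyte are computed on non-outlying values
    by one-pass trimming, then a single detection sweep is run — no
    iteration, so the flagged set is deterministic.
    """
    arr = values.to_numpy(float)
    mask = np.zeros_like(arr, dtype=bool)
    for j in range(arr.shape[1]):
        obs = ~np.isnan(arr[:, j])
        if obs.sum() < 3:
            continue
        m, s = _trimmed_moments(arr[obs, j], z_cutoff)
        if s == 0:
            continue
        mask[obs, j] = np.abs(arr[obs, j] - m) / s > z_cutoff
    return pd.DataFrame(mask, index=values.index, columns=values.columns)


def impute_outliers_nn(table: CohortTable, z_cutoff: float = 5.0,
                       k: int = 5) -> tuple[CohortTable, QCReport]:
    """Replace >z_cutoff-SD cells by the mean of the k nearest subjects.

    Nearness is Euclidean distance over all *other* analytes, standardized
    by their trimmed moments, averaged over the co-observed columns of the
    two subjects. Neighbour values are restricted to non-outlying cells of
    the same analyte, which guarantees the imputed cell is itself within
    the cutoff.
    """
    out = table.copy()
    arr = out.values.to_numpy(float)
    n, p = arr.shape
    outliers = detect_outliers(out.values, z_cutoff).to_numpy()

    # standardized matrix for distances; outliers excluded so they cannot
    # drag their own neighbourhood
    zmat = np.full_like(arr, np.nan)
    for j in range(p):
        obs = ~np.isnan(arr[:, j])
        if obs.sum() < 3:
            continue
        m, s = _trimmed_moments(arr[obs, j], z_cutoff)
        if s > 0:
            zmat[obs, j] = (arr[obs, j] - m) / s
    zmat[outliers] = np.nan

    records = []
    for j in range(p):
        col_out = np.nonzero(outliers[:, j])[0]
        if len(col_out) == 0:
            continue
        donors = np.nonzero(~np.isnan(arr[:, j]) & ~outliers[:, j])[0]
        if len(donors) == 0:
            raise ValueError(
                f"all observed values of analyte {out.analytes[j]!r} are outlying; "
                "cannot impute")
        other = np.delete(np.arange(p), j)
        for i in col_out:
            zi = zmat[i, other]
            zd = zmat[np.ix_(donors, other)]
            diff = zd - zi[None, :]
            shared = ~np.isnan(diff)
            counts = shared.sum(axis=1)
            with np.errstate(invalid="ignore"):
                d2 = np.where(shared, diff ** 2, 0.0).sum(axis=1) / np.maximum(counts, 1)
            d2[counts == 0] = np.inf
            order = np.argsort(d2, kind="stable")
            nbr = donors[order[: min(k, len(donors))]]
            imputed = float(np.mean(arr[nbr, j]))
            records.append((out.values.index[i], out.analytes[j],
                            float(arr[i, j]), imputed))
            arr[i, j] = imputed

    out.values = pd.DataFrame(arr, index=out.values.index, columns=out.values.columns)
    report = QCReport(
        per_analyte=pd.DataFrame(index=out.values.columns.rename("analyte")),
        outlier_cells=pd.DataFrame(
            records, columns=["subject_id", "analyte", "original", "imputed"]),
    )
    if records:
        logger.info("imputed %d outlier cells in %d subjects",
                    len(records), len({r[0] for r in records}))
    return out, report


# ---------------------------------------------------------------------------
# 4. Box-Cox transform selection
# ---------------------------------------------------------------------------

def select_transform(values: np.ndarray, analyte: str = "",
                     min_n: int = 20) -> TransformSpec:
    """Choose identity or log10 for one analyte by Box-Cox analysis.

    The Box-Cox lambda is estimated by maximum likelihood with a
    profile-likelihood 95% CI; log10 is chosen when the CI excludes 1 and
    the point estimate is closer to 0 than to 1 (|lambda| < 0.5) —
    i.e. the data look log-normal rather than normal. Nonpositive values
    force identity (log10 undefined); a constant vector is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) > 0 and np.all(x == x[0]):
        raise ValueError("constant vector: Box-Cox fit undefined")
    if (x <= 0).any():
        return TransformSpec(analyte, "identity", None, None, "nonpositive_values")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} positive observations, got {len(x)}")
    _, lam, ci = stats.boxcox(x, alpha=0.05)
    lo, hi = float(ci[0]), float(ci[1])
    if (1.0 < lo or 1.0 > hi) and abs(lam) < 0.5:
        return TransformSpec(analyte, "log10", float(lam), (lo, hi), "ci_excludes_1")
    return TransformSpec(analyte, "identity", float(lam), (lo, hi), "compatible_with_normal")


def select_transforms(table: CohortTable, min_n: int = 20) -> pd.DataFrame:
    """Run transform selection for every analyte; returns a spec table."""
    rows = []
    for name in table.analytes:
        spec = select_transform(table.values[name].to_numpy(float), name, min_n)
        rows.append({
            "analyte": spec.analyte,
            "transform": spec.transform,
            "lambda": spec.lam,
            "ci_low": None if spec.ci is None else spec.ci[0],
            "ci_high": None if spec.ci is None else spec.ci[1],
            "rationale": spec.rationale,
        })
    return pd.DataFrame(rows).set_index("analyte")


def apply_transforms(table: CohortTable, specs: pd.DataFrame) -> pd.DataFrame:
    """Analysis-scale value matrix: log10 where the spec says so."""
    out = table.values.copy().astype(float)
    for name in out.columns:
        if name in specs.index and specs.loc[name, "transform"] == "log10":
            out[name] = np.log10(out[name])
    return out


# ---------------------------------------------------------------------------
# Full pass
# ---------------------------------------------------------------------------

def run_qc(table: CohortTable, missing_threshold: float = 0.10,
           z_cutoff: float = 5.0, k: int = 5,
           ) -> tuple[CohortTable, QCReport, pd.DataFrame]:
    """Measurability filter -> LDL/2 -> outlier NN imputation -> transforms.

    Returns the cleaned table (retained analytes only, raw scale), the
    combined QC report, and the per-analyte transform spec table. The
    number of subjects and the retained analyte columns never change
    between steps 2-4; only cell values do.
    """
    meas = flag_measurable(table, missing_threshold)
    kept = table.subset_analytes(meas.retained)
    if kept.n_analytes == 0:
        raise ValueError("no analytes survive the measurability filter")
    kept, ldl_cells = impute_below_ldl_table(kept)
    kept, outlier_report = impute_outliers_nn(kept, z_cutoff, k)
    specs = select_transforms(kept)
    report = QCReport(
        per_analyte=meas.per_analyte,
        below_ldl_cells=ldl_cells,
        outlier_cells=outlier_report.outlier_cells,
    )
    return kept, report, specs
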