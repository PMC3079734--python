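"""Covariate-adjusted group-difference screen and correlation tables.

For each analyte, an analysis of covariance compares CDR 0 against the
pooled CDR > 0 group while adjusting for age at lumbar puncture and
gender; least-squares (adjusted) means are evaluated at the whole-sample
covariate means and back-transformed (10^LSmean) for log10 analytes.
Significance is Bonferroni-corrected over the declared family of tests.
Spearman correlations against reference markers and Mann-Whitney gender
differences reproduce the descriptive companion tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable


class RankDeficientDesign(ValueError):
    """The ANCOVA design matrix is singular; names the offending column."""


# ---------------------------------------------------------------------------
# ANCOVA screen
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # find a column whose removal restores full rank
        for j, name in enumerate(names):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X):
                raise RankDeficientDesign(
                    f"design is rank deficient; column {name!r} is collinear")
        raise RankDeficientDesign("design is rank deficient")


def ancova_analyte(y: np.ndarray, group: np.ndarray, age: np.ndarray,
                   female: np.ndarray, log10_scale: bool = False) -> dict:
    """Fit ``value ~ group + age + gender`` for one analyte by least squares.

    Returns the partial-F p-value for the group effect (1 df, so F = t^2),
    adjusted means per group at the sample covariate means (back-transformed
    when the analyte was analysed on the log10 scale), raw group means, and
    interaction p-values from a secondary model with group x age and
    group x gender terms.
    """
    obs = ~np.isnan(y)
    y, group, age, female = y[obs], group[obs], age[obs], female[obs]
    for g in (0, 1):
        if (group == g).sum() < 3:
            raise ValueError("need at least 3 subjects per group")
    X = np.column_stack([np.ones_like(y), group, age, female])
    _check_rank(X, ["intercept", "group", "age", "gender"])
    fit = sm.OLS(y, X).fit()
    t_group = fit.tvalues[1]
    f_group = t_group ** 2
    p_group = float(fit.pvalues[1])
    age_bar, female_bar = age.mean(), female.mean()
    b = fit.params
    ls0 = b[0] + b[2] * age_bar + b[3] * female_bar
    ls1 = ls0 + b[1]
    if log10_scale:
        adj0, adj1 = 10.0 ** ls0, 10.0 ** ls1
        raw0 = float(np.mean(10.0 ** y[group == 0]))
        raw1 = float(np.mean(10.0 ** y[group == 1]))
    else:
        adj0, adj1 = float(ls0), float(ls1)
        raw0 = float(np.mean(y[group == 0]))
        raw1 = float(np.mean(y[group == 1]))

    Xi = np.column_stack([X, group * age, group * female])
    fit_i = sm.OLS(y, Xi).fit()
    return {
        "f_group": float(f_group),
        "p": p_group,
        "adj_mean_cdr0": float(adj0),
        "adj_mean_cdr_gt0": float(adj1),
        "raw_mean_cdr0": raw0,
        "raw_mean_cdr_gt0": raw1,
        "p_group_x_age": float(fit_i.pvalues[4]),
        "p_group_x_gender": float(fit_i.pvalues[5]),
        "n": int(len(y)),
    }


def ancova_screen(table: CohortTable, transforms: pd.DataFrame | None = None,
                  alpha: float = 0.05, n_tests: int | None = None,
                  ) -> pd.DataFrame:
    """Run the ANCOVA screen over every analyte (CDR 0 vs CDR>0).

    Missing cells are dropped casewise per analyte. ``n_tests`` defaults to
    the number of analytes screened; the returned table carries the raw p,
    the Bonferroni flag at ``alpha / n_tests``, adjusted and raw group
    means, and the interaction p-values.
    """
    group = table.impaired().to_numpy(float)
    age = table.demographics["age_at_lp"].to_numpy(float)
    female = table.female_indicator().to_numpy(float)
    if n_tests is None:
        n_tests = table.n_analytes
    cutoff = bonferroni_threshold(alpha, n_tests)[0]
    rows = []
    for name in table.analytes:
        is_log = (transforms is not None and name in transforms.index
                  and transforms.loc[name, "transform"] == "log10")
        y = table.values[name].to_numpy(float)
        if is_log:
            y = np.log10(y)
        res = ancova_analyte(y, group, age, female, log10_scale=is_log)
        res["analyte"] = name
        res["transform"] = "log10" if is_log else "identity"
        res["bonferroni_significant"] = res["p"] < cutoff
        rows.append(res)
    out = pd.DataFrame(rows).set_index("analyte")
    cols = ["transform", "adj_mean_cdr0", "adj_mean_cdr_gt0", "raw_mean_cdr0",
            "raw_mean_cdr_gt0", "f_group", "p", "bonferroni_significant",
            "p_group_x_age", "p_group_x_gender", "n"]
    return out[cols].sort_values("p")


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 128,
                         ) -> tuple[float, str]:
    """Per-test cutoff alpha/n_tests, plus its one-significant-digit display.

    (0.05, 128) gives 0.000390625, displayed as "0.0004".
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    cutoff = alpha / n_tests
    exponent = int(np.floor(np.log10(cutoff)))
    rounded = round(cutoff, -exponent)
    display = np.format_float_positional(rounded, trim="-")
    return cutoff, display


# ---------------------------------------------------------------------------
# Correlation / gender-difference tables
# ---------------------------------------------------------------------------

def spearman_screen(table: CohortTable, reference_markers: pd.DataFrame,
                    min_pairs: int = 10) -> pd.DataFrame:
    """Spearman rho (average ranks for ties) of each analyte against each
    reference marker, with two-sided t-approximation p-values and pairwise
    deletion of missing values; plus the Mann-Whitney gender-difference p.

    Analyte/reference pairs with fewer than ``min_pairs`` complete pairs
    are flagged and their rho omitted (NaN).
    """
    female = table.female_indicator().to_numpy(float)
    rows = []
    for name in table.analytes:
        x = table.values[name].to_numpy(float)
        row: dict = {"analyte": name}
        for ref in reference_markers.columns:
            r = reference_markers[ref].to_numpy(float)
            obs = ~np.isnan(x) & ~np.isnan(r)
            if obs.sum() < min_pairs:
                row[f"rho_{ref}"] = np.nan
                row[f"p_{ref}"] = np.nan
                row[f"flag_{ref}"] = "insufficient_pairs"
                continue
            rho, p = stats.spearmanr(x[obs], r[obs])
            row[f"rho_{ref}"] = float(rho)
            row[f"p_{ref}"] = float(p)
            row[f"flag_{ref}"] = ""
        obs = ~np.isnan(x)
        if (female[obs] == 1).any() and (female[obs] == 0).any():
            row["p_gender"] = gender_difference(x[obs], female[obs])
        else:
            row["p_gender"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("analyte")


def gender_difference(values: np.ndarray, female: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value for a female vs male level difference,
    using the tie-corrected normal approximation."""
    values = np.asarray(values, dtype=float)
    female = np.asarray(female)
    a = values[female == 1]
    b = values[female == 0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both genders must be present")
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(p)
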