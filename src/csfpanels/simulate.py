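"""Synthetic multiplex-CSF cohort generator with ground truth.

Emulates the statistical structure the downstream analyses assume: three
Clinical Dementia Rating groups (defaults 242 / 63 / 28 for CDR 0 / 0.5 / 1),
~125 measurable analytes whose latent values load on two factors — a
"tau-like" factor most analytes correlate with and an "amyloid-like" factor
few do — plus group mean shifts on a subset of truly informative analytes,
age and gender effects, below-detection-limit censoring, sporadic
missingness, rare >5-SD outliers, and exponential proportional-hazards
conversion times for the cognitively normal subgroup.

Every generated cohort comes with a :class:`TruthRecord` from which the
implied group moments, optimal panel combinations and hazard coefficients
are recomputable in closed form, so each pipeline stage can be tested for
parameter recovery without the study's (undeposited) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CohortTable, FollowUpRecord

LN10 = np.log(10.0)


@dataclass
class SimScenario:
    """Parameters of the cohort generator.

    Per-analyte arrays left as None are materialized deterministically from
    the structural parameters (same scenario -> same arrays), so a scenario
    plus a seed fully determines a cohort.
    """

    n_per_group: tuple[int, int, int] = (242, 63, 28)  # CDR 0 / 0.5 / 1
    n_analytes: int = 125
    n_signal: int = 12
    effect_sizes: np.ndarray | None = None      # latent-SD shift per signal analyte
    factor_loadings: np.ndarray | None = None   # (n_analytes, 2)
    age_effect: np.ndarray | None = None        # latent SD per year
    gender_effect: np.ndarray | None = None     # latent SD, female vs male
    ldl_quantile: float = 0.01                  # censoring fraction in the CDR 0 group
    missing_rate: float = 0.005
    outlier_rate: float = 0.002                 # ~82 outliers over 333 x 125 cells
    lognormal_flags: np.ndarray | None = None
    # demographics, per CDR group
    age_means: tuple[float, float, float] = (71.6, 74.6, 76.8)
    age_sds: tuple[float, float, float] = (7.4, 7.3, 6.2)
    female_fracs: tuple[float, float, float] = (0.65, 0.52, 0.50)
    e4_fracs: tuple[float, float, float] = (0.32, 0.54, 0.57)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group counts must be positive")
        if not 0 <= self.n_signal <= self.n_analytes:
            raise ValueError("n_signal must lie in [0, n_analytes]")
        for name in ("ldl_quantile", "missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0,1), got {v}")
        rng = np.random.default_rng(12345)  # scenario-level defaults, fixed
        p = self.n_analytes
        if self.effect_sizes is None:
            # strongest markers shift ~1 latent SD, tail ~0.3 SD
            self.effect_sizes = (np.linspace(1.0, 0.3, self.n_signal)
                                 if self.n_signal else np.empty(0))
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if len(self.effect_sizes) != self.n_signal:
            raise ValueError("effect_sizes length must equal n_signal")
        if self.factor_loadings is None:
            load = np.zeros((p, 2))
            tau_like = rng.random(p) < 0.6
            amyloid_like = (~tau_like) & (rng.random(p) < 0.25)
            load[tau_like, 0] = rng.uniform(0.3, 0.7, tau_like.sum())
            load[amyloid_like, 1] = rng.uniform(0.3, 0.6, amyloid_like.sum())
            self.factor_loadings = load
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        if self.factor_loadings.shape != (p, 2):
            raise ValueError("factor_loadings must have shape (n_analytes, 2)")
        if (np.abs(self.factor_loadings) > 1).any():
            raise ValueError("|factor loadings| must be <= 1")
        if ((self.factor_loadings ** 2).sum(axis=1) > 1).any():
            raise ValueError("loadings imply a non-positive-semidefinite covariance")
        if self.age_effect is None:
            slopes = np.where(rng.random(p) < 0.5, rng.uniform(0.01, 0.04, p), 0.0)
            self.age_effect = slopes
        self.age_effect = np.asarray(self.age_effect, dtype=float)
        if self.gender_effect is None:
            self.gender_effect = np.where(rng.random(p) < 0.35,
                                          rng.uniform(-0.4, 0.4, p), 0.0)
        self.gender_effect = np.asarray(self.gender_effect, dtype=float)
        if self.lognormal_flags is None:
            self.lognormal_flags = rng.random(p) < 0.5
        self.lognormal_flags = np.asarray(self.lognormal_flags, dtype=bool)
        for name in ("age_effect", "gender_effect", "lognormal_flags"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} must have length n_analytes")

    # ------------------------------------------------------------------
    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent Gaussian implied by the factor model."""
        lam = self.factor_loadings
        sigma = lam @ lam.T
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def latent_shifts(self) -> np.ndarray:
        """Per-analyte CDR>0 vs CDR 0 mean shift on the latent SD scale."""
        shifts = np.zeros(self.n_analytes)
        shifts[: self.n_signal] = self.effect_sizes
        return shifts


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated cohort."""

    signal_analytes: list[str]
    latent_shifts: np.ndarray                 # per analyte, CDR>0 minus CDR 0
    latent_correlation: np.ndarray
    lognormal: np.ndarray
    scale_mu: np.ndarray                      # analyte location on its native scale
    scale_sigma: np.ndarray                   # analyte scale on its native scale
    analytes: list[str]
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    cox_betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float | None = None

    def analysis_scale_sd(self, j: int) -> float:
        """SD of analyte j on the scale the screen analyses it (log10 or raw)."""
        return self.scale_sigma[j] / LN10 if self.lognormal[j] else self.scale_sigma[j]

    def true_binormal(self, panel: Sequence[str]):
        """Closed-form (mu0, mu1, Sigma, AUC) of a panel on its analysis scale.

        Log-normal analytes enter on the log10 scale; the latent correlation
        structure is shared by both CDR groups, so the optimal-combination
        AUC is Phi(sqrt(delta' (2 Sigma)^-1 delta)).
        """
        idx = [self.analytes.index(m) for m in panel]
        sd = np.array([self.analysis_scale_sd(j) for j in idx])
        mu0 = np.array([
            self.scale_mu[j] / LN10 if self.lognormal[j] else self.scale_mu[j]
            for j in idx
        ])
        delta = self.latent_shifts[idx] * sd
        corr = self.latent_correlation[np.ix_(idx, idx)]
        sigma = corr * np.outer(sd, sd)
        mu1 = mu0 + delta
        auc = float(norm.cdf(np.sqrt(delta @ np.linalg.solve(2 * sigma, delta))))
        return mu0, mu1, sigma, auc


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal_ages(rng, mean, sd, n, lower=60.0):
    ages = mean + sd * rng.standard_normal(n)
    while (ages < lower).any():
        bad = ages < lower
        ages[bad] = mean + sd * rng.standard_normal(bad.sum())
    return ages


def generate_cohort(scenario: SimScenario, seed: int) -> tuple[CohortTable, TruthRecord]:
    """Draw a cohort from the latent-factor model with censoring and artifacts.

    The latent value of subject i on analyte j is
    ``lam_j . F_i + sqrt(1 - |lam_j|^2) eps_ij + shift_j * 1[CDR>0]
    + age_effect_j (age_i - 72) + gender_effect_j * female_i``; it is mapped
    to a concentration by ``mu_j + sigma_j z`` (normal analytes) or
    ``exp(mu_j + sigma_j z)`` (log-normal analytes). Values below the LDL —
    set at the ``ldl_quantile`` of the CDR 0 marginal — are emitted as
    censored; missingness and >5-SD outliers are then injected at the
    scenario rates.
    """
    rng = np.random.default_rng(seed)
    p = scenario.n_analytes
    groups = np.repeat([0.0, 0.5, 1.0], scenario.n_per_group)
    n = len(groups)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    analytes = [f"A{j:03d}" for j in range(p)]

    # demographics
    age = np.empty(n)
    female = np.empty(n)
    e4 = np.empty(n, dtype=bool)
    start = 0
    for g, ng in enumerate(scenario.n_per_group):
        sl = slice(start, start + ng)
        age[sl] = _truncated_normal_ages(rng, scenario.age_means[g],
                                         scenario.age_sds[g], ng)
        female[sl] = rng.random(ng) < scenario.female_fracs[g]
        e4[sl] = rng.random(ng) < scenario.e4_fracs[g]
        start += ng
    demo = pd.DataFrame(
        {
            "age_at_lp": np.round(age, 1),
            "gender": np.where(female == 1, "female", "male"),
            "apoe": np.where(e4, "e3e4", "e3e3"),
            "cdr": groups,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    # latent Gaussian: two common factors + independent noise
    lam = scenario.factor_loadings
    uniq = np.sqrt(1.0 - (lam ** 2).sum(axis=1))
    factors = rng.standard_normal((n, 2))
    z = factors @ lam.T + rng.standard_normal((n, p)) * uniq
    shifts = scenario.latent_shifts()
    z += np.outer(groups > 0, shifts)
    z += np.outer(age - 72.0, scenario.age_effect)
    z += np.outer(female, scenario.gender_effect)

    # native concentration scales
    srng = np.random.default_rng(98765)  # per-analyte scales, scenario-fixed
    mu = np.where(scenario.lognormal_flags,
                  srng.uniform(np.log(5.0), np.log(2000.0), p),
                  srng.uniform(50.0, 1000.0, p))
    sigma = np.where(scenario.lognormal_flags,
                     srng.uniform(0.3, 0.8, p),
                     mu * srng.uniform(0.15, 0.30, p))
    conc = mu[None, :] + sigma[None, :] * z
    ln = scenario.lognormal_flags
    conc[:, ln] = np.exp(mu[None, ln] + sigma[None, ln] * z[:, ln])

    # lower detection limits at the CDR 0 marginal quantile
    q = scenario.ldl_quantile
    zq = norm.ppf(max(q, 1e-12))
    ldl = np.where(scenario.lognormal_flags,
                   np.exp(mu + sigma * zq), mu + sigma * zq)
    ldl = np.maximum(ldl, 1e-6)  # LDL must be positive even for deep quantiles

    below = conc < ldl[None, :]
    values = np.where(below, np.nan, conc)

    truth = TruthRecord(
        signal_analytes=analytes[: scenario.n_signal],
        latent_shifts=shifts,
        latent_correlation=scenario.latent_correlation(),
        lognormal=scenario.lognormal_flags.copy(),
        scale_mu=mu,
        scale_sigma=sigma,
        analytes=analytes,
    )

    # sporadic missingness
    miss = (rng.random((n, p)) < scenario.missing_rate) & ~below
    values[miss] = np.nan
    truth.missing_cells = [(subject_ids[i], analytes[j]) for i, j in zip(*np.nonzero(miss))]

    # rare extreme outliers: replace with mean + U(5.5, 8) sample SDs
    can_outlie = ~np.isnan(values)
    out = (rng.random((n, p)) < scenario.outlier_rate) & can_outlie
    if out.any():
        col_mean = np.nanmean(values, axis=0)
        col_sd = np.nanstd(values, axis=0, ddof=1)
        mag = rng.uniform(5.5, 8.0, out.sum())
        sign = np.where(rng.random(out.sum()) < 0.5, -1.0, 1.0)
        ii, jj = np.nonzero(out)
        shifted = col_mean[jj] + sign * mag * col_sd[jj]
        # keep outliers above the LDL so they stay "observed"
        shifted = np.where(shifted <= ldl[jj], col_mean[jj] + mag * col_sd[jj], shifted)
        values[ii, jj] = shifted
        truth.outlier_cells = [(subject_ids[i], analytes[j]) for i, j in zip(ii, jj)]

    meta = pd.DataFrame(
        {"unit": ["pg/mL"] * p, "ldl": ldl},
        index=pd.Index(analytes, name="analyte"),
    )
    table = CohortTable(
        demographics=demo,
        values=pd.DataFrame(values, index=demo.index, columns=analytes),
        below_ldl=pd.DataFrame(below, index=demo.index, columns=analytes),
        analyte_meta=meta,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Conversion-time generation
# ---------------------------------------------------------------------------

def generate_survival(cohort: CohortTable,
                      true_betas: dict[str, float],
                      baseline_hazard: float,
                      n_visits: int = 10,
                      visit_interval: float = 1.0,
                      followup_fraction: float = 1.0,
                      seed: int = 0,
                      truth: TruthRecord | None = None,
                      ) -> tuple[list[FollowUpRecord], TruthRecord | None]:
    """Draw CDR 0 -> CDR>0 conversion times under proportional hazards.

    The linear predictor is ``sum_m beta_m * Z_m`` over Z-scored analyte
    columns (Z computed within the CDR 0 analysis set; the key ``"age"``
    uses centred raw years so its beta is per year). Latent times are
    exponential with rate ``baseline_hazard * exp(lp)``; conversion is
    observed at the first scheduled visit after the latent time, and
    subjects whose latent time exceeds the last visit are censored there.
    ``followup_fraction`` < 1 drops a random subset to mimic subjects with
    no follow-up assessment.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    cdr0 = cohort.demographics.index[cohort.demographics["cdr"] == 0]
    if len(cdr0) == 0:
        raise ValueError("cohort has no CDR 0 subjects")
    if followup_fraction < 1.0:
        keep = rng.random(len(cdr0)) < followup_fraction
        cdr0 = cdr0[keep]

    lp = np.zeros(len(cdr0))
    for name, beta in true_betas.items():
        if name == "age":
            x = cohort.demographics.loc[cdr0, "age_at_lp"].to_numpy(float)
            lp += beta * (x - x.mean())
        else:
            if name not in cohort.values.columns:
                raise ValueError(f"true_betas references unknown marker {name!r}")
            x = cohort.values.loc[cdr0, name].to_numpy(float)
            mean = np.nanmean(x)
            x = np.where(np.isnan(x), mean, x)  # rare missing -> mean, keeps lp defined
            lp += beta * (x - mean) / np.std(x, ddof=1)

    t_latent = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    horizon = n_visits * visit_interval
    records = []
    for sid, t in zip(cdr0, t_latent):
        if t <= horizon:
            k = int(np.ceil(t / visit_interval))
            records.append(FollowUpRecord(sid, max(k, 1) * visit_interval, True))
        else:
            records.append(FollowUpRecord(sid, horizon, False))
    if truth is not None:
        truth.cox_betas = dict(true_betas)
        truth.baseline_hazard = baseline_hazard
    return records, truth


# ---------------------------------------------------------------------------
# QC fixture
# ---------------------------------------------------------------------------

def make_qc_fixture(n_analytes: int = 190, n_unmeasurable: int = 65,
                    n_subjects: int = 333, seed: int = 0) -> CohortTable:
    """Cohort in which exactly ``n_unmeasurable`` analytes fail the 10% rule.

    Unmeasurable analytes get strictly more than 10% of cells missing or
    below the LDL; all others get at most 10%.
    """
    if n_unmeasurable > n_analytes:
        raise ValueError("n_unmeasurable cannot exceed n_analytes")
    rng = np.random.default_rng(seed)
    analytes = [f"A{j:03d}" for j in range(n_analytes)]
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    limit = int(np.floor(0.10 * n_subjects))  # max affected cells while measurable

    values = 100.0 + 10.0 * rng.standard_normal((n_subjects, n_analytes))
    below = np.zeros((n_subjects, n_analytes), dtype=bool)
    for j in range(n_analytes):
        if j < n_unmeasurable:
            n_bad = int(rng.integers(limit + 1, min(n_subjects, 2 * limit + 2)))
        else:
            n_bad = int(rng.integers(0, limit + 1))
        rows = rng.choice(n_subjects, size=n_bad, replace=False)
        half = n_bad // 2
        values[rows[:half], j] = np.nan                      # missing
        below[rows[half:], j] = True                         # below-LDL
        values[rows[half:], j] = np.nan

    demo = pd.DataFrame(
        {
            "age_at_lp": np.round(rng.uniform(60, 90, n_subjects), 1),
            "gender": np.where(rng.random(n_subjects) < 0.6, "female", "male"),
            "apoe": np.where(rng.random(n_subjects) < 0.4, "e3e4", "e3e3"),
            "cdr": np.where(np.arange(n_subjects) < int(0.73 * n_subjects), 0.0, 0.5),
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    meta = pd.DataFrame(
        {"unit": ["pg/mL"] * n_analytes, "ldl": np.full(n_analytes, 50.0)},
        index=pd.Index(analytes, name="analyte"),
    )
    return CohortTable(
        demographics=demo,
        values=pd.DataFrame(values, index=demo.index, columns=analytes),
        below_ldl=pd.DataFrame(below, index=demo.index, columns=analytes),
        analyte_meta=meta,
    )
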