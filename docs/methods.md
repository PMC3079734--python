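# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the procedure was genuinely open, and what the
synthetic-cohort tests do and do not establish about real data.

## Cohort model and file dialect

A cohort is a wide table: one row per subject with age at lumbar
puncture (years), gender, APOE genotype (ε4 positivity = any ε4 allele),
Clinical Dementia Rating (CDR 0 / 0.5 / 1), and one concentration column
per analyte; a sidecar records each analyte's unit and lower detection
limit (LDL > 0). Files are comma-separated UTF-8 with "." decimals; an
empty cell or `NA` is missing, and `<x` marks a below-LDL measurement,
so censoring survives a round trip. Analytes are never unit-normalized
against each other: every analyte is analyzed on its own recorded scale
(concentration units differ across assays and carry no shared meaning).
Gender is stored as a string in files and as a female indicator
internally. All group contrasts pool CDR 0.5 and CDR 1 into a single
CDR > 0 class; the CDR 1 stratum alone is too small to analyze.

## Quality control

The pass order is fixed and is part of the contract, because the LDL and
outlier steps do not commute:

1. **Measurability.** Missing and below-LDL cells are pooled; an analyte
   is excluded when the pooled fraction strictly exceeds 10%. Exactly
   10.0% is retained.
2. **LDL/2 imputation.** Censored cells of retained analytes become
   LDL/2. Truly missing cells stay missing and are handled per analysis
   by casewise deletion — no multivariate imputation of missingness is
   attempted, since only the censoring rule has a defensible physical
   justification (a censored value is known to lie in (0, LDL)).
3. **Outliers.** Per analyte, reference moments come from one pass of
   trimming (provisional > 5 SD cells removed, moments recomputed), then
   a single detection sweep flags cells with |z| > 5. No iteration: the
   flagged set is deterministic. Flagged cells are replaced by the mean
   of the analyte in the k = 5 nearest subjects, nearness measured by
   Euclidean distance over the other retained analytes standardized by
   their trimmed moments and averaged over co-observed columns. Donor
   values are restricted to non-outlying cells, which guarantees the
   imputed value itself respects the cutoff. The rule runs on the raw
   concentration scale, before any transform; this is an assumption (the
   order relative to transformation is not dictated by the procedure)
   and is flagged in the QC report.
4. **Transform selection.** Box–Cox maximum likelihood (λ̂ with a
   profile-likelihood 95% CI, via `scipy.stats.boxcox`). log10 is chosen
   when the CI excludes 1 *and* |λ̂| < 0.5 — i.e. the data are
   incompatible with normality and closer to log-normality; otherwise
   identity. Nonpositive values force identity with a recorded
   rationale; a constant vector (e.g. an analyte entirely below LDL) is
   an error rather than a silent pass-through. The 0.5 cutoff
   operationalizes "transform when appropriate": λ within ±0.5 of 0 is
   treated as log-like, within the CI's power to distinguish.

A second QC pass over cleaned data changes nothing (idempotence), and no
step ever changes the table's shape — only cell values.

## Covariate-adjusted screen

Per analyte (log10-transformed where the spec says so), the linear model
`value ~ group + age + female` is fitted by ordinary least squares
(statsmodels), with the group effect tested by partial F (1 df, so
F = t²). Adjusted means are least-squares means at the whole-sample
covariate means, with gender at its sample proportion — the standard
LS-means convention; log-scale LS means are back-transformed as
10^LSmean, which estimates the group geometric mean, not the arithmetic
mean. A secondary model adds group×age and group×gender; its interaction
p-values are reported descriptively and never alter the main screen.
Multiplicity is handled by Bonferroni only; the family size defaults to
128 (the 125 measurable panel analytes plus the three classical CSF
markers) and is exposed in configuration because ratio markers could
arguably be counted as well. The displayed cutoff rounds the exact
α/n to one significant digit (0.05/128 = 0.000390625 → 0.0004).
Spearman correlations (average ranks, t-approximation p, pairwise
deletion, ≥ 10 pairs) and Mann–Whitney gender differences (tie-corrected
normal approximation) fill the descriptive companion tables.

## Binormal optimal-combination ROC panels

Within each class a panel is modeled as multivariate Gaussian with
sample means and unbiased sample covariances. The linear combination
maximizing the AUC under this model (the Su–Liu / optimal-combination
solution) is a ∝ (Σ₀+Σ₁)⁻¹δ with δ = μ₁−μ₀, stored unit-norm with the
sign making aᵀδ ≥ 0 so the analytic AUC = Φ(√(δᵀ(Σ₀+Σ₁)⁻¹δ)) is ≥ 0.5.
Sensitivity at specificity q uses the Gaussian class-score
distributions. The empirical AUC is the Mann–Whitney estimator with ties
counted ½ (raw orientation preserved; an oriented variant is provided
separately), and the empirical sensitivity interpolates the ROC curve at
the target false-positive rate.

Panels are evaluated by a stratified bootstrap, resampling with
replacement within each CDR class at the original class sizes — the
design ratio (242 : 91 at study scale) is part of what the bootstrap
must preserve. Each of the B = 100 iterations refits the panel and its
nested 2-marker reduction, records the analytic AUC, the binormal
sensitivity at 80% specificity, and a p-value for the AUC gain. Two
method choices were open and are resolved as follows:

- **Confidence intervals** are normal-theory intervals on the bootstrap
  mean (mean ± 1.96·SD/√B), i.e. the dispersion of the B iteration
  values, matching the "averages over bootstrap iterations" reporting
  style rather than the original closed-form CI of the combination
  method, which the workflow being reproduced does not specify.
- **The ΔAUC p-value** per iteration is a one-sided paired DeLong test
  on the two panels' combination scores over the shared resampled
  subjects (placement-value covariance); identical panels are degenerate
  by definition and report p = 1. The mechanism behind the published
  per-panel p-values is unstated; a paired empirical-AUC test on shared
  subjects is the field-standard choice.

Degenerate resamples (singular fitted covariance) are redrawn and
counted. Derived ratio markers (e.g. tau/Aβ42) are computed on raw
concentrations before transform selection, then log10-transformed.
Panel expansion is the targeted scheme: the top `n_base` 2-marker panels
are crossed with the top `n_candidates` single markers, skipping a
candidate already inside its base (so 4 bases × 10 candidates with one
collision yield 39 panels), ordered deterministically by ranks.

## Classification harness

The evaluation protocol, not the learners, is the contribution: 200
stratified 80/20 train/test splits; any tuning happens by 5 inner splits
of the training portion only; age, gender and APOE ε4 status are always
appended to the predictor set; per-split sensitivity/specificity are
taken at the argmax-posterior operating point (0.5 score cut — the
published protocol does not state the cut), AUC from held-out scores;
means over splits are reported and the Youden identity
J = sens + spec − 1 holds row by row and for the means (J is linear).

Three reference classifiers are native:

- **Nearest shrunken centroids**: standardized class-centroid
  differences dₖ = (x̄ₖ − x̄)/(mₖ(s + s₀)) with mₖ = √(1/nₖ − 1/n) and
  s₀ = median(s), soft-thresholded at Δ; prediction by the standardized
  discriminant with log class priors; the shrinkage grid is 30 values on
  [0.325, 9.097]. Its built-in importance statistic is the surviving
  features' |shrunken difference|.
- **k-NN** on standardized predictors, k tuned over 5–15, score = the
  positive-class vote fraction.
- **Naive Bayes** with Gaussian class conditionals, or kernel-density
  conditionals using one pooled Silverman bandwidth per feature shared
  by both classes (so an arbitrarily wide kernel flattens the likelihood
  ratio and the posterior tends to the priors), accumulated in log
  space.

External learners (random forests, boosted trees, SVM, PLS, logistic
regression, ...) attach through a thin adapter around any scikit-learn
estimator; they must supply their own importance rankings. Top-k
importance overlap is plain set arithmetic (pairwise, global, and
against an external reference list such as the ROC-stage panel markers).

## Prognosis

Baseline marker values of CDR 0 subjects with follow-up are Z-scored
over that analysis subset (not the full cohort — the analysis population
defines the SD unit; a configuration switch could widen this, and AIC
ordering is invariant to the choice since Z-scoring is affine). Age
enters in raw years so its HR is per year. Markers whose *low* values
raise risk enter as reciprocals (1/x before log/Z), making their HR > 1.

Cox models are fitted by lifelines (Newton–Raphson on the partial
likelihood, Efron tie handling — annual-visit conversion times are
heavily tied, so Breslow would be noticeably biased), with Wald CIs and
p-values and AIC = −2 log PL + 2·(number of covariates). Selection is
staged: (1) univariate screen at p < 0.15; (2) survivors with Spearman
|ρ| ≥ 0.4 and p < 0.05 are never co-included — each maximal
conflict-free subset becomes an alternative candidate model (the 0.4
threshold generalizes the observed exclusion of a pair at ρ = 0.476 and
is exposed in configuration); (3) backward pruning drops the worst
covariate at p ≥ 0.05 one at a time, with age, gender and ε4 status
always entered and re-tested but droppable; (4) models are ranked by
AIC, all reported, lowest flagged. The overall panel HR is the product
of component HRs — identically exp(Σβ̂) — reported to 3 decimals.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume,
not any real assay. Latent analyte values are Gaussian with a 2-factor
covariance: most analytes load on a "tau-like" factor, a minority on an
"amyloid-like" factor (loadings must satisfy |λ|² ≤ 1 per analyte or the
model is rejected as non-PSD), reproducing the observed pattern that
many panel analytes correlate with CSF tau/p-tau and few with Aβ42.
Group shifts act on the latent SD scale for the first `n_signal`
analytes; age and gender act as per-analyte linear effects. Latent
values map to concentrations affinely (normal analytes) or
exponentially (log-normal analytes, about half by default). Defaults are
the study conditions: 242/63/28 subjects per CDR group, 125 analytes,
group-specific age distributions (means 71.6/74.6/76.8, truncated at
60), female fractions 65/52/50%, ε4 fractions 32/54/57%.

Artifacts are injected in this order: LDL censoring (the LDL sits at the
1% quantile of the CDR 0 marginal, so no emitted value lies strictly
between 0 and the LDL), sporadic missingness (0.5% of cells), and rare
extreme outliers (rate 0.002 ≈ 82 expected over 333 × 125 cells, the
observed contamination scale) implemented as mean ± U(5.5, 8) sample
SDs so the 5-SD rule is guaranteed to see them. Per-analyte effect sizes
default to a linear ramp from 1.0 down to 0.3 latent SDs across the
signal analytes, bracketing the strong (tau-like, d ≈ 1) and marginal
ends of the observed screen.

Conversion times for CDR 0 subjects are exponential proportional-hazards
draws with linear predictor Σ βₘ·Zₘ (age centred, per year); events are
observed at the first annual visit after the latent time and subjects
are censored at the last scheduled visit — matching annual clinical
assessment and producing the heavy ties Efron handling is for. In
recovery tests the baseline hazard is 0.04–0.05/yr over 10 visits,
giving ~80–100 events at n = 215: richer than the observed 29/215
conversion count, a deliberate identifiability choice so that
fixed-seed selection tests measure the selector, not event-count noise;
the closed-form converter-count check runs at the observed 0.02/yr
scale.

Every generated cohort carries a truth record from which group moments,
optimal-combination AUCs and hazard coefficients are recomputable in
closed form. What passing tests show: the estimators recover the
generating parameters of a latent-Gaussian factor cohort with censoring,
missingness and contamination. What they do not show: robustness to
assay drift, plate effects, non-Gaussian latent structure, or
informative missingness — none of which the generator emulates.

## Numerical choices and degenerate inputs

- Seeds: one run seed, spawned per stage via `numpy.random.SeedSequence`;
  equal config + seed reproduces every output byte (manifests carry no
  timestamps).
- Singular Σ₀+Σ₁ (condition number > 1e12) raises; `fit_binormal` can
  ridge-regularize on request, logging the epsilon. A zero-separation
  panel returns AUC 0.5 with an arbitrary unit direction.
- Rank-deficient ANCOVA designs (e.g. single-gender cohorts) raise a
  named-column error rather than silently dropping a term.
- Bonferroni display rounds to one significant digit; the exact cutoff
  is always used for flagging.
- The profile-likelihood CI for Box–Cox uses α = 0.05 throughout.
- Problem sizes in the test suite are scaled (e.g. 12–40 analytes,
  B = 10–100, 6–15 splits) with study-scale sizes (n = 333, 125
  analytes, n = 2000 for recovery) reserved for the statistical
  acceptance checks; each test states its size.

## Known limitations

- The binormal model is assumed, not tested, by the panel stage; heavily
  skewed markers should arrive log-transformed (the QC stage usually
  ensures this, but an identity-scale heavy tail will degrade the
  closed-form AUC's accuracy).
- The bootstrap p-value for nested panels is approximate twice over
  (DeLong normal approximation within iterations, averaging across
  iterations); it is a ranking device, not a calibrated test.
- No FDR option; the screen is Bonferroni-only by design.
- Native classifiers are reference implementations for the protocol, not
  tuned competitors; serious model comparisons should attach external
  learners through the adapter.
- Cox models assume proportional hazards and handle neither
  time-varying covariates nor competing risks.
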