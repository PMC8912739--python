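# Methods

This note records the statistical model the package implements, the
generative model behind the synthetic cohorts, the defaults and why they
were chosen, and the numerical decisions that a user reproducing or
extending the analysis should know about.

## 1. Study design and analysis model

The package targets the population-based case–control design: incident
cases plus controls frequency-matched on age and sex, analysed by
unconditional logistic regression with the matching factors forced into
every model,

    logit P(D=1 | E, G, C) = α + β_E' x_E + β_G G + γ' C.

* **Exposure** `E` — an ordinal 4-level intake variable
  (`<=1/week` [reference], `multiple/week`, `1/day`, `>1/day`), entered
  as treatment contrasts. A "per category increase" trend uses the codes
  0–3 linearly.
* **PRS** `G` — the unweighted sum of risk-allele dosages over a panel
  of independent loci (140 by default), ranked to percentiles against a
  reference population. `β_G` is the log-odds per single percentile;
  models may code the term per 10 percentiles, and all genetic-risk-
  equivalent output is rescaled to single percentiles regardless.
* **Covariates** `C` — chosen by bidirectional AIC search (below) from
  the study's questionnaire covariates; age enters continuously, sex and
  the binary covariates as indicators, education/BMI/smoking as
  3-level categoricals.

Percentile reference population: controls by default (they approximate
the source population of a case–control study), with a pooled-sample
option. The published analysis does not state its reference; the choice
is surfaced in `StudyConfig.prs_reference` and recorded in the report
provenance. Percentiles use mean ranks for ties,
`100 · (c_less + (c_eq + 1)/2) / n_ref`, capped at 100 for scores beyond
the reference maximum; category cuts sit exactly at the 10th, 25th,
75th and 90th percentiles.

### Stepwise AIC

Greedy bidirectional search: starting from the forced terms, every
single-term addition and deletion is evaluated, the move with the lowest
AIC is taken if it strictly improves the current AIC, and the search
stops otherwise. Forced terms are never eligible for deletion, rows are
fixed to complete cases over *all* candidate variables so AICs are
comparable, candidate fits that fail to converge are skipped with a
warning, and ties break on sorted term order — the procedure is a
deterministic function of the data. For a 1-df candidate, admission is
equivalent to a likelihood-ratio statistic exceeding 2, i.e. a marginal
inclusion probability of P(χ²₁ > 2) ≈ 0.157 for pure noise; the test
suite checks exactly this rate.

### Interaction and joint effects

Multiplicative interaction is tested by adding all cross-products of the
two term groups and jointly testing the block — likelihood-ratio by
default, Wald optionally (3 df for 4-level exposure × continuous PRS,
12 df for 4-level × 5-level PRS). Joint effects re-code the data as a
20-cell factor (5 PRS strata × 4 intake levels) with the
(medium, `<=1/week`) cell as the uniform reference; any cell lacking
observations in both arms is a named error rather than a silent NA.

## 2. Genetic risk equivalents

GRE_k = β_Ek / β_G, in PRS percentiles. Three confidence intervals:

* **Delta** (default): first-order Taylor variance
  `SE² = v_E/β_G² + β_E² v_G/β_G⁴ − 2 β_E c_EG/β_G³`, normal critical
  values, symmetric about the point estimate. Chosen as the default
  because every interval of the published site/stage table is symmetric
  to the printed precision — the signature of a delta construction — and
  because it matches the risk/rate-advancement-period tradition this
  statistic descends from.
* **Fieller**: roots of
  `(β_G² − z²v_G)ρ² − 2(β_Eβ_G − z²c_EG)ρ + (β_E² − z²v_E)`. When the
  PRS coefficient is not significant at the level, the confidence set is
  unbounded (complement of an interval, or the whole line) and is
  reported as such rather than forced into a finite pair.
* **Parametric bootstrap**: percentile interval of the ratio over
  multivariate-normal draws of `(β_E, β_G)`.

**Accuracy regime.** With `t = |β_G|/SE_G`, Fieller tracks the bootstrap
essentially exactly at any `t`; the delta interval is within 5% relative
width of both only for `t ≳ 9` (at `t = 5` it is ~12% narrow, because
the first-order expansion drops the ratio's skewness). In this analysis
class the PRS is strongly associated (`t` well above 10), so the delta
default is safe; for weak denominators use Fieller or the bootstrap.
The cross-validation tests exercise the three-way agreement at `t ≥ 10`.

GREs require the PRS as a continuous covariate; a categorical PRS term
is a named error. The reference intake level is reported as `Ref.`, not
as GRE 0.

## 3. The synthetic-cohort generator

The generator emulates the stated world of the motivating study class:

* subjects drawn i.i.d. from a super-population; disease by a logistic
  model whose intercept is calibrated (by root-finding on the first
  streamed chunk, size 100 000) to a configurable population prevalence;
* all cases up to `n_cases` retained, controls subsampled — optionally
  frequency-matched on age decade × sex (decades clipped to ≤49 … ≥80 so
  sparse tails never starve a stratum; largest-remainder allocation of
  per-stratum targets). Shortfalls raise explicit errors, never silent
  truncation;
* a 140-locus dosage matrix of Hardy–Weinberg Binomial(2, f) draws,
  frequencies U(0.05, 0.95) unless supplied, with optional clipped
  Gaussian jitter emulating imputed dosages;
* the 4-level exposure from a latent-logistic threshold model at the
  published control prevalences (0.117 / 0.609 / 0.244 / 0.031,
  normalised from the printed counts), with a configurable
  latent-shift knob that correlates intake with the smoking/alcohol
  covariates to create confounding (off by default);
* a covariate panel (education, BMI, smoking, alcohol, diabetes, family
  history, colonoscopy, NSAIDs, statins) at the published control
  prevalences, with default log-ORs fixed once at epidemiologically
  plausible values (e.g. current smoking +0.40, colonoscopy −0.70);
* optional missing-exposure injection; the pipeline excludes such rows
  and logs the count, mirroring the study's exclusion rule.

**The truth scale of β_G.** The generative PRS percentile is evaluated
against the *analytic* population distribution of the score — the exact
convolution of the per-locus trinomial distributions, read off as the
mid-distribution CDF `100·(P(S<s) + P(S=s)/2)` (smoothed with the locus-
sum Gaussian when jitter is on). This makes
`beta_prs_per_percentile` exactly defined, independent of pool size, and
lets recovery tests compare the fitted slope to a fixed truth.

**Default prevalence 0.05.** The population prevalence is a free
parameter of the design (a case–control study has none of its own). The
default is deliberately small so that controls approximate the source
population: the fitted model ranks percentiles against controls, the
truth is defined on population percentiles, and at 5% prevalence the
two scales agree closely enough that the PRS slope estimator is
unbiased to well within simulation tolerances. Raising the prevalence
makes generation cheaper but progressively distorts the control-rank
scale.

Default effect sizes are the published adjusted estimates — exposure
log-ORs (ln 1.19, ln 1.41, ln 1.73), PRS slope 0.0131/percentile (the
value implied by the published top-intake OR 1.74 and GRE 42.3), age
+0.03/year, male +0.30 — so the default world's true GREs are
13.3 / 26.2 / 41.8 percentiles.

What the generator does **not** emulate: linkage disequilibrium between
loci (draws are independent), genotyping error or a real imputation
model, dose–response measurement error in the food-frequency exposure,
correlated covariate structure beyond the single confounding knob, and
secular/recruitment effects. A green simulation suite therefore
establishes that the estimators and tests behave correctly under the
stated statistical structure — not that any real dataset satisfies that
structure.

## 4. Numerical choices and edge cases

* Logistic fits: statsmodels Newton iterations, gradient tolerance 1e-8,
  max 100 iterations; observed-information covariance. Perfect
  separation and non-convergence raise `ConvergenceError`; rank-deficient
  designs raise `RankDeficiencyError` naming the aliased columns (QR
  diagnostic).
* Complete-case analysis per model; dropped-row counts are kept on the
  fitted object and in report provenance, and per-model
  `n_used + n_dropped` must reconcile with the input size.
* AIC = 2k − 2ℓ with k including the intercept.
* Fieller's bounded case computes `max(disc, 0)` before the square root:
  when the denominator is significant the discriminant is non-negative
  analytically, but rounding can leave it at −1e-17.
* Delta variance < 0 (possible only with an inconsistent covariance
  input) is an error, not an NaN.
* Same-seed runs are byte-identical, file for file; the streaming chunk
  size is a fixed constant because changing it would change the draw
  order.
* Site (proximal colon / distal colon / rectum / unknown) and stage
  (I–III / IV / unknown) are assigned to cases at the published case
  mix, independent of exposure and PRS — consistent with the published
  finding of no site/stage heterogeneity. Site/stage-specific models
  restrict cases to the subset and keep all controls.

## 5. Open design points, resolved

* **Exposure-item combination.** The rule combining red-meat and
  processed-meat questionnaire items into one 4-level variable is not
  published in the main text; the generator emits the combined variable
  directly. This is an assumption, not a reconstruction.
* **Percentile reference** (controls vs pooled): configurable, default
  controls, logged.
* **Interaction p-values** (LRT vs Wald): both provided, LRT default; a
  joint block test matches the single published p per comparison.
* **Age coding**: continuous, as the simplest form consistent with
  forcing a matching factor; the published coding is unstated.
* **Subgroup models** use the selected covariate set minus the
  stratifier itself, and Table-3-style stratum analyses reuse
  whole-sample percentiles rather than re-ranking within stratum.
* **Multiple testing**: none across subgroups, matching the published
  presentation; the report footer says so.

## 6. Known limitations

* The delta CI understates ratio skewness for weakly identified PRS
  coefficients (see §2); the implementation warns by construction —
  Fieller's unbounded flag — rather than numerically.
* Stepwise AIC inherits the usual post-selection caveats: reported CIs
  for selected covariates are conditional on the selected model.
* The generator's frequency matching is exact at the stratum level but
  leaves residual within-decade age differences; models therefore still
  adjust for continuous age.
* At small cohort sizes (≲1500 subjects) the sparse cells of the joint
  5×4 grid and the very-low/very-high PRS strata make those sections of
  the report unstable or unestimable; the pipeline surfaces this as
  named cell/stratum errors or notes rather than smoothing over it.
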