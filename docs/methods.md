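# Methods

## What the package computes

`survcut` implements a standardized procedure for turning a continuous
gene-expression marker into a frozen prognostic decision rule for overall
survival (OS), in the setting where it was developed: intermediate
cytogenetic risk acute myeloid leukemia (AML) and the markers BAALC, ERG,
MN1 and EVI1. The procedure has four stages:

1. **Standardization.** Probe-set intensity matrices are chip-normalized
   (each sample column scaled so its 2%-trimmed mean equals 500), log2
   transformed, geometric-mean-centered per probe set, z-scored per probe
   set (mean 0, SD 1), and averaged into per-gene scores using a fixed
   gene → probe-set map. The fitted centering and scale constants form a
   reference model, so a single new case can be scored against a frozen
   reference without re-fitting — the property that makes the assay usable
   for individual patients.
2. **Discovery.** For a candidate gene, the cohort is repeatedly (default
   1000×) split at random into 50% train / 50% test halves. At each
   percentile of a fixed grid (10th–90th in steps of 5), the expression
   threshold is computed on the train half, the test half is dichotomized
   at it, and a two-sided logrank test is applied to the test half. The
   fraction of repetitions with p < α (α = 0.05) per percentile is the
   *significance profile*; its peaks are candidate cutoffs.
3. **Lockdown.** A training-profile peak is locked only if an independent
   verification cohort's profile supports it (fraction ≥ `min_support`,
   default 0.20; the best-supported peak wins, ties to the lower
   percentile). The chosen percentile is translated into an expression
   value, which — not the percentile — is the frozen rule. For extremely
   right-skewed markers such as EVI1 (a small high-expression spike on a
   low-expression bulk), the profile has no power; the threshold is instead
   the candidate midpoint between consecutive distinct expression values
   that maximizes the logrank statistic, subject to a minimum high-group
   size, with ties broken toward the larger threshold.
4. **Validation.** The frozen threshold classifies an independent cohort
   into low/high expressers (scores exactly at the threshold are "low").
   The rule passes if the one-sided logrank p in the prespecified adverse
   direction is ≤ 0.05. The report includes the high-vs-low hazard ratio
   with Wald 95% CI, both Kaplan-Meier curves, mutation-enrichment 2×2
   tables (Fisher's exact), and multivariate Cox models, optionally refit
   after excluding a stratum (e.g. all high-EVI1 cases).

## Statistical components

* **Logrank test** — standard O−E form with hypergeometric variance at tied
  event times; two-sided p from χ²(1). The one-sided p is half the
  two-sided p when the observed excess of events lies in the prespecified
  adverse group, else 1 − half. Prior direction: high EVI1/ERG/MN1 adverse;
  for BAALC the low stratum is adverse (the direction the validation data
  support), so reported high-vs-low HRs for BAALC fall below 1.
* **Cox proportional hazards** — Newton-Raphson with step halving on the
  Breslow partial likelihood; Wald CIs and p-values from the inverse
  observed information. Breslow tie handling was chosen for determinism and
  closed-form simplicity; with continuous simulated times it coincides with
  Efron. Constant or collinear covariates raise an error naming the
  offending columns; monotone likelihood (complete separation, |β| > 15 or
  divergence during iteration) is reported as a non-estimable fit rather
  than an exception. Missing covariate values are rejected, not imputed.
* **Fisher's exact test** — two-sided by the "sum of small p" convention
  (all tables in the hypergeometric support with probability ≤ observed ×
  (1 + 10⁻⁷)), delegated to `scipy.stats.fisher_exact` and verified
  exhaustively against full-support enumeration for every table with total
  ≤ 40.
* **Kaplan-Meier** — product-limit estimation via lifelines, re-shaped to
  expose at-risk and event counts at each distinct event time.
* **Percentile convention** — linear interpolation between closest ranks
  over (n − 1) intervals (the NumPy default), monotone in p. Population SD
  (÷ n) in the z-scoring step. Both conventions are configurable; the
  procedure that produced the historical thresholds did not document its
  choices, so determinism across implementations was the deciding concern.

## The synthetic cohort generator

Because the original cohorts (147 training, 242 verification, 215
validation cases) are external, every stage is exercised on simulated
cohorts with the structure the analysis assumes:

* **Expression.** BAALC/ERG/MN1 are standard normal, mirroring their
  near-normal standardized distributions. The EVI1-like marker is a
  two-component mixture: baseline N(−0.25, 0.40²) and a spike
  N(2.5, 0.6²) entered with probability 12/215 ≈ 5.6%, reproducing the
  extreme right skew with a small overexpressing subgroup that straddles
  the historical threshold 0.987.
* **Survival.** Exponential event times per stratum: the planted threshold
  (a percentile of the generated scores) splits the cohort, and the adverse
  stratum's hazard is `baseline_hazard × hazard_ratio`. This makes the
  model exactly proportional-hazards with closed-form medians (ln 2 / λ),
  so hazard ratios and median ratios are analytically checkable. Censoring
  is an independent exponential (`censor_rate`) plus an administrative cap
  (`max_followup`). Defaults: baseline hazard 0.025/month (median OS ≈ 28
  months), censoring 0.012/month, cap 120 months — chosen once for
  plausibility for adult intermediate-risk AML (roughly two-thirds of
  reference-stratum cases die in follow-up); the source cohorts' censoring
  and follow-up were never published, so these are plausibility choices,
  not calibrated ones.
* **EFS.** Event-free survival is OS with an additional earlier event
  process (default 0.008/month, sharing the stratum hazard ratio). No
  attempt is made to model relapse biology; the endpoint is a generic
  earlier-event time.
* **Mutations.** NPM1, CEBPA double-mutant and FLT3-ITD indicators are
  Bernoulli draws at stratum-specific frequencies; presets use the
  published stratified frequencies (e.g. NPM1 49/81 in low-BAALC vs 36/134
  in high-BAALC cases).
* **Covariates.** Age, gender, WBC, marrow blast % and platelets are drawn
  independently of expression by default. A `confounding` knob shifts the
  adverse stratum's age and tilts the hazard through age (log-hazard
  0.03/year), so adjusted and unadjusted estimates separate for
  confounding-recovery experiments.
* **Reproducibility.** One integer seed; every sub-stream (per gene, OS,
  EFS, mutations, covariates) is derived deterministically from it via
  spawned `SeedSequence`s, so identical configurations are bitwise
  reproducible and adding a gene does not perturb the others' draws.

What the generator deliberately does **not** emulate: probe-level intensity
noise, batch effects, cytogenetic substructure, non-proportional hazards,
informative censoring, or correlation between expression markers. Passing
tests therefore demonstrate that the *machinery* is correct under the
assumed data model, not that the historical cohort results are reproduced.

## Numerical and design choices

* **CV thresholds from the train half.** Computing the percentile threshold
  on the full cohort inside each repetition would leak test-half
  information into the threshold; the train half is used, at the cost of
  slight extra threshold noise.
* **Degenerate splits** (empty or event-free test-half group) count as
  non-significant — keeping the denominator at `n_reps` — and are tallied
  separately per percentile.
* **Profile argmax under plateaus.** With strong planted effects the
  per-percentile power saturates and several grid points tie at the
  maximum. The argmax is therefore located at the *median* tied position
  (lower-middle for even ties), a plateau-robust convention fixed before
  any recovery experiment was run. Strict peaks (for lockdown) are defined
  separately: a point must strictly exceed its neighbors, ties yield no
  peak, and endpoints qualify against their single neighbor.
* **Repetition count matters for recovery.** At 200 repetitions the
  fraction resolution (0.005) leaves exact ties at 1.0 across the plateau
  and the argmax wanders; at the procedure's native 1000 repetitions the
  underlying power ordering (maximal at the planted percentile) resolves.
  Profiles used for recovery experiments therefore run 1000 repetitions.
* **Per-cohort profiles are not binomially calibrated.** Under the null the
  *expected* significant fraction is α, but repetitions are random splits
  of one cohort, so the per-cohort fraction is over-dispersed relative to
  Binomial(n_reps, α): a cohort with a chance expression–survival
  association yields a high fraction at many percentiles at once. Type-I
  calibration is therefore assessed over independent null cohorts (one
  split each), where binomial consistency genuinely holds. This is also why
  a verification cohort is required before lockdown: a single cohort's
  profile can look convincing by chance.
* **Boundary rules.** Classification is strict (score > threshold ⇒ high);
  discovery counts a repetition significant when p < α strictly, while
  validation passes at p ≤ 0.05 — both as the procedure defines them.
* **min_support = 0.20** for verification support: between the supported
  (23%) and unsupported (~7–10%) fractions observed when the procedure was
  originally applied; configurable.

## Problem sizes

Simulation-based tests and the acceptance script use: null calibration over
200 independent 300-case cohorts; planted-cutoff recovery over 50 cohorts
of 300 cases at 1000 CV repetitions each; Cox CI coverage over 100
replicates at n = 300; exhaustive brute-force comparisons at n ≤ 60
(maximal cutoff) and table totals ≤ 40 (Fisher). These sizes are the
package's own study conditions and are stated here so results are
reproducible as printed.

## Known limitations

* The logrank p is asymptotic (χ²(1)); at very small n (≈ 12) it can
  differ from the exact permutation p by several hundredths — inherent to
  the test, not to this implementation, which matches lifelines to 1e-6.
* Wald intervals (not likelihood-ratio or profile) throughout; no
  correction for the multiplicity of the 17 grid points, and no selection
  correction for the maximally selected statistic — the procedure's design
  is to validate externally instead.
* EFS event definitions, competing risks, Efron/exact ties and
  time-varying covariates are out of scope.
* The historical thresholds (−0.95 for BAALC, −0.76 for MN1, 0.987 for
  EVI1) are reproducible only with the original cohort data; the package
  treats them as frozen inputs when applying rules, and reproduces the
  *procedure* that generated them on synthetic data.
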