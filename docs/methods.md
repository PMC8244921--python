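# Methods note

This note documents the statistical models implemented in `tonegenes`,
the assumptions they make, the defaults chosen and why, and the numerical
methods behind them. It describes the package's own behaviour; no claim
here is an empirical statement about real linguistic or genetic data.

## 1. Data harmonization

### 1.1 Allele frequencies

Locus-level measurements for one genetic sample and gene are pooled by the
sample-size-weighted average

    wavg = Σᵢ fᵢ·Nᵢ / Σᵢ Nᵢ ,

where `fᵢ` is a reported derived-allele frequency and `Nᵢ` the number of
genotyped alleles (≈ 2 × individuals). Assumptions:

* Proxy SNPs are treated as interchangeable with their target variants;
  imperfect linkage disequilibrium is ignored in the pooling. The
  `exclude_proxies` switch supports the sensitivity analysis that drops
  proxy loci instead.
* Missing frequencies are never imputed: a sample without a measurement
  for a gene simply has no row for it.
* The packaged `data/proxy_snps.tsv` map resolves each locus to its gene
  and role (target/proxy); loci absent from the map are excluded with a
  warning rather than silently kept.

### 1.2 Tone codings

Five source schemes are recoded into `tone1` (No/Yes), `tone3way`
(None < Simple < Complex) and an integer `count`:

* WALS three-way labels map directly onto `tone3way`.
* LAPSyD labels collapse Marginal with Simple; a numeric LAPSyD value is
  the gold-standard count.
* PHOIBLE counts: 0 → None, ≤ 2 → Simple, else Complex.
* WPHON counts: 0 → None, ≤ 3 → Simple, else Complex (its counting
  convention runs one higher).
* DL2007 supplies only the binary coding.

Counts from non-gold sources are **rebased** (1 collapsed with 2, then all
counts ≥ 2 shifted down by one, yielding 0 → 0, 1 → 1, n → n−1) and
**aligned** to the gold scale through a quadratic regression
`gold = β₀ + β₁·c + β₂·c²`. The packaged default alignment coefficients
are (0.08, 0.92, −0.04) for WPHON and (0.39, 0.68, −0.04) for PHOIBLE;
`fit_count_alignment` refits them from paired data when available.
Aligned predictions are rounded half-away-from-zero and floored at 0 —
a fixed, documented convention so that harmonized counts are reproducible
integers.

Sources are reconciled per glottocode purely by precedence ("the highest
available source wins"), with defaults LAPSyD ≥ WALS ≥ DL2007 ≥ WPHON ≥
PHOIBLE for categorical codings and LAPSyD ≥ WPHON ≥ PHOIBLE for counts;
alternative hierarchies are provided for robustness checks. Coarser
codings are deduced from finer ones (count → three-way → binary) when no
source supplies them directly; missing stays missing.

### 1.3 Analysis table

Samples map to glottocodes many-to-many, so the merge is a Cartesian
expansion annotated with Glottolog family and macroarea; North and South
America collapse into a single America macroarea. Deduplication then
removes rows that duplicate signal for the chosen outcome: within a
sample, glottocodes with the same outcome value collapse to one row;
within a (meta)population, samples with identical (ASPM-D, MCPH1-D)
frequency pairs collapse to one row. Equality is exact by design (label
equality, floating-point equality) — near-duplicates are treated as
genuine variation, never fuzzily merged. z-scores (`aspm_z`, `mcph1_z`,
ddof = 1) are computed on the final, deduplicated subset, so each outcome
dataset carries its own standardization.

## 2. Regression models

### 2.1 Families

* `binomial`: logistic regression for `tone1`/`tone2`.
* `poisson`: log-linear regression for tone counts.
* `beta`: Beta regression (mean–precision parameterization, logit link on
  the mean) for allele frequencies; exact 0/1 values are pulled inside the
  open interval by `beta_boundary_adjust` (0 → 1e−7, 1 → 1−1e−7), the
  smallest perturbation that keeps the likelihood finite.

### 2.2 Random-intercept GLMM

Genealogical clustering is modelled by a language-family random intercept
`u_g ~ N(0, σ²)`. The marginal likelihood is computed by **adaptive
Gauss–Hermite quadrature**: per group, an inner Newton iteration finds the
posterior mode of `u_g` (vectorized over groups via grouped sums, warm-
started between optimizer steps), the integrand is re-centred and re-scaled
at that mode, and a K-node Hermite rule integrates it (K = 15 by default;
K = 1 is the Laplace approximation). The outer optimization is L-BFGS-B
over `[β, (log φ), log σ]`, with `log σ` bounded in `[log 1e−6, log 50]`.
Standard errors come from the numerically differentiated observed
information (central differences); Wald p-values are normal-based. With
`σ` pinned to 0 the fit reproduces the fixed-effects GLM likelihood
exactly, which the test suite uses as an internal consistency check; the
suite also validates the binomial GLMM against `lme4::glmer` with 15-node
adaptive quadrature (agreement to ≈ 1e−3 on coefficients and
log-likelihood on a study-sized dataset).

### 2.3 Variance decompositions

The **adjusted ICC** is `σ²_F / (σ²_F + resid)` on the latent scale, with
distribution-specific residual variances: π²/3 for logistic,
`ln(1 + 1/λ₀)` for Poisson (λ₀ from the null-model intercept), and
`ψ₁(μφ) + ψ₁((1−μ)φ)` (trigamma) for Beta — the variance of `logit(y)`
under the fitted Beta law at the intercept-implied mean. The adjusted ICC
is defined on the null model only (random effects alone); requesting it
from a model with fixed terms raises an error rather than returning a
conditional quantity with a misleading name. **Marginal R²**
(Nakagawa) is `var(Xβ) / (var(Xβ) + σ²_F + resid)`.

### 2.4 Power

`power_by_simulation` simulates outcomes from a specified GLMM (fixed
effects, family variance) on the actual covariate/family structure —
optionally counterfactually enlarged by replicating families or languages
— refits the analysis model, and reports the rejection fraction of the
Wald test for one coefficient with a 95% Clopper–Pearson interval.

## 3. Resampling

### 3.1 Constrained permutations

Eighteen scenarios cross three axes: **what** is permuted (the tone
outcome; both allele columns together as linked pairs; each allele
independently) × **within which strata** (unrestricted; within macroareas;
within families) × whether the refitted model **controls for macroarea**
as a fixed effect. Scenario names are three-letter codes (T/L/I, U/M/F,
N/F; e.g. `TUN`, `IMF`). Each permutation is a multiset-preserving
rearrangement within strata; the summary reports the percentage of
permuted refits with strictly lower AIC and strictly smaller (more
negative) allele coefficients than the observed fit. Failed refits are
dropped from the denominator; more than 10% failures aborts the scenario.
`run_all_scenarios` gives each scenario an independent child RNG stream
(`SeedSequence.spawn`), so results are reproducible and scenario-order
independent.

### 3.2 Restricted sampling

Repeatedly drawing exactly one uniformly chosen language per family breaks
within-family dependence, so plain fixed-effects GLMs apply. Per allele,
three model variants are fitted (allele alone; + macroarea; + macroarea +
the other allele) and the coefficient distribution is summarized
(mean/median/SD, % negative). The same one-row-per-family resampling
drives the restricted variants of mediation and path analysis.

## 4. Mediation

Treatment = Africa indicator, mediator = one z-scored allele frequency,
outcome = a tone coding. A linear mediator model and a GLM outcome model
(binomial/poisson/gaussian) are fitted; parameters are drawn from their
asymptotic normal distributions (quasi-Bayesian Monte Carlo, 1000 draws by
default); counterfactual mediator values under treatment and control share
unit-level mediator noise and are pushed through the outcome mean
function. ACME, ADE and TE (= ADE + ACME) are reported on the response
scale (probability differences for binary outcomes) with percentile CIs
and Monte-Carlo two-sided p-values. `prop_mediated = ACME/TE` is reported
only when the TE interval excludes 0, because the ratio is unstable
otherwise.

## 5. Path analysis

The recursive system `MV1 = a1·IV`, `MV2 = a2·IV`,
`DV = c′·IV + b1·MV1 + b2·MV2` with *uncorrelated* mediator residuals has
one degree of freedom (10 sample moments, 9 free parameters). Because the
system is recursive with diagonal residual covariance, ML path estimates
coincide with equation-wise OLS; the χ² statistic is `(n−1)·F_ML`
comparing the implied covariance to the biased (1/n) sample covariance —
the standard normal-theory SEM convention. Incremental indices (CFI,
TLI = NNFI, RFI) use the independence baseline over the same four
variables (df = 6); CFI is clipped to [0, 1]. Coefficients are
standardized by the sample SDs of the analysis subset. Freeing the
mediator residual covariance gives the just-identified variant: χ² = 0,
df = 0, indices undefined (NaN). Binary variables are treated as numeric
0/1 — the normal-theory χ² is then approximate, which is why the
calibration tests generate Gaussian systems.

## 6. Synthetic-data generator

The generator emulates the sampling structure the analyses are designed
for, with defaults matching the study-like regime used throughout the test
suite:

| Parameter | Default | Rationale |
|---|---|---|
| `n_families` | 35 | study-scale number of families |
| `languages_per_family` | zero-truncated geometric, mean 5.2 | ≈ 181 expected rows; heavy right tail like real family sizes |
| `macroarea_weights` | Africa .2, Eurasia .6, America .1, Papunesia .1 | Eurasia-dominated sampling, each family in exactly one macroarea |
| `allele_macroarea_means` (logit) | aspm: −2.2/−0.2/0.0/−0.5; mcph1: −2.5/1.0/1.5/0.5 | strong Africa-vs-rest frequency contrast, larger for MCPH1-D |
| `allele_family_sd` | aspm 0.6, mcph1 1.2 | family clustering of frequencies (high ICC, higher for MCPH1-D) |
| `allele_precision` (Beta φ) | aspm 30, mcph1 100 | sample-level measurement noise; ∞ short-circuits to the noise-free mean |
| `tone_intercept`, `beta_aspm`, `beta_mcph1` | −1.0, −1.0, 0.0 | minority-tone baseline; a −1 logit effect of ASPM-D; null MCPH1-D |
| `tone_family_sd` | 2.77 | σ² ≈ 7.68, i.e. latent logistic ICC ≈ 0.7 |
| `count_model` | intercept 0.4, beta_aspm −0.3, family_sd 1.0 | Poisson channel with the same qualitative structure |
| `shared_population_prob` | 0.15 | occasional many-samples-per-population mapping |
| `consistent_codings` | True | hurdle coupling: count = 0 ⇔ tone1 = "No", as in harmonized codings |

One RNG stream (`numpy` `default_rng(seed)`) drives all stages, so a
(config, seed) pair yields byte-identical datasets. `tone3way` derives
from counts (0 → None, ≤ 2 → Simple, else Complex) and `tone2` is Complex
vs rest. With `consistent_codings=True` the Poisson channel is truncated
by the binary channel, so Poisson-parameter recovery tests should set it
to `False`; the default favours realism of the harmonized codings over
marginal distributional purity.

## 7. Problem sizes in the test suite

The calibration tests run at deliberately reduced but statistically
meaningful scales chosen by this package (uniformity of permutation
p-values: 200 replicates × 200 permutations on n = 100 fixed-effects
fits; parameter recovery and CI coverage: 200 replicates at the default
35-family scale; path-model calibration: 300–400 replicates of n = 300;
power sanity: 300–400 simulated refits). Tolerances are pre-registered
bands implied by binomial Monte-Carlo error at those sizes (e.g. a
rejection-rate band of [2%, 9%] around a nominal 5% with ≈1% standard
error), not post-hoc adjustments.

## 8. Limitations

* LD imperfection between proxies and targets is ignored by design; the
  proxy-exclusion switch is the only sensitivity lever.
* The GLMM supports a single random intercept (family); no crossed or
  nested random effects, and no random slopes.
* Wald CIs from the numerically differentiated observed information can
  undercover slightly at a few dozen groups; the restricted-sampling and
  permutation machinery exist precisely as complementary inference.
* Mediation assumes sequential ignorability (no unmeasured
  treatment–mediator or mediator–outcome confounding) — untestable, and
  surely optimistic for macroarea-level "treatments".
* The path model's normal-theory χ² is approximate for binary codings and
  ignores the clustering the mixed models handle; its restricted-sampling
  variant mitigates the latter only.
* The deduplication rule relies on exact equality; independently reported
  but numerically distinct measurements of the same population are kept
  as separate rows.
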