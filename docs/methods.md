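# Methods

This note documents the statistical models behind `prs-transfer`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real-data behaviour.

## Scoring and standardisation

The score is the linear predictor `PRS_i = Σ_k β_k x_ik` over effect-allele
dosages in [0, 2]. Dosage sources may count either allele of a variant;
variants are matched to the weight panel by identifier first and alleles
second, and a column whose counted allele is the panel's *other* allele is
flipped (`x → 2 − x`) before the weighted sum. Palindromic (A/T, C/G)
variants are therefore accepted on the identifier match by default; a
strict mode rejects them when the allele pair disagrees with the panel.
Missing dosages for resolvable variants are a hard error: the intended
inputs are fully imputed datasets, and silent mean-imputation would bias
the score downward for exactly the variants where imputation is least
trustworthy.

Standardisation divides by a reference-control SD with **no**
mean-centering, so that group means remain interpretable on the reference
scale and odds ratios read per reference SD. SDs use the unbiased (n−1)
estimator, the epidemiological convention. When the variant set shrinks
(imputation-quality filtering at INFO < 0.9, or restriction to the variants
a dosage source carries), weights are deliberately not renormalised: scores
built on nested variant sets remain directly comparable, which is the
convention this style of analysis uses when reporting, say, a 287-SNP and a
229-SNP version of the same score.

## Association statistics

* **Per-SD and percentile-bin ORs.** Maximum-likelihood logistic
  regression (IRLS, convergence tolerance 1e−8, 100 iterations max) with
  Wald 95% CIs; default covariates are ten principal components plus
  study/array/batch stratum indicators. Percentile bins are defined by
  control-distribution quantiles (numpy's default linear/type-7 rule)
  applied to everyone; a value exactly at a cut point goes to the upper
  bin. The 40–60% bin is the reference and is reported with OR exactly 1.
* **Prospective hazard ratios.** Cox partial likelihood on the age scale
  with delayed entry (left truncation at entry age) and Efron tie
  handling, via lifelines.
* **Study-adjusted AUC.** Concordance restricted to within-stratum
  case–control pairs (ties ½), pooled across strata with pair-count
  weights. Exact published software behaviour for this adjustment is not
  fully specified anywhere; the pair-pooled definition used here is the
  natural nonparametric reading and is verified against exhaustive pair
  enumeration.
* **Meta-analysis.** Inverse-variance fixed-effect pooling. Heterogeneity
  uses the fixed-effect weights: Q = Σ w_i (b_i − b̄)², I² = max(0,
  (Q−df)/Q)·100, p from χ²(k−1). This is a moment-based simplification of
  the generalised-Q random-effects estimator some analyses quote; the two
  agree closely at small heterogeneity, and the simplification is
  deliberate.
* **Interaction tests.** Wald z on the product term. Some published
  analyses label these "Student's t"; asymptotically the two coincide.
* **Family-history attenuation.** OR for first-degree family history with
  and without the PRS as a covariate; attenuation is on the log scale,
  `100·(ln OR_unadj − ln OR_adj)/ln OR_unadj`, and is flagged undefined
  when the unadjusted OR does not exceed 1.

## The multiplicative polygenic model

With γ the log OR per control SD, the rare-disease normal-shift model puts
cases at N(γ, 1) and controls at N(0, 1) in control-SD units. Predicted bin
ORs are ratios of normal masses; λ_P = exp(γ²/2); the explained fraction of
a familial relative risk λ is γ²/(2 ln λ); the model AUC is Φ(γ/√2).

Two interpretation points are worth making explicit:

* γ enters all formulas as a **log** odds ratio. Published prose often
  says "OR per SD" while the arithmetic (e.g. an ~11% familial fraction
  from an OR of 1.48 against λ = 2) is only consistent with γ = ln(OR);
  `PolygenicModel.from_or_per_sd` performs the conversion.
* The γ for an analysed population standardised to a *reference* SD is
  `ln(OR_per_reference_SD) · control_sd / reference_sd`, i.e. the effect
  is first moved onto the analysed population's own SD scale.

A finite-prevalence mode integrates the exact logistic-model case and
control densities numerically instead of using the normal shift; at
prevalences of a few percent the two agree to well under one percent in
the extreme bins, so the shift approximation is the default and the exact
mode mainly serves the Monte-Carlo cross-checks.

## Absolute risk with competing mortality

On a one-year age grid, hazards are treated as annual probabilities.
Calibration of group hazards to the population incidence is a single
forward age recursion,

    λ*(u) = λ_pop(u) · Σ_g f_g S_g(u) / Σ_g f_g S_g(u) r_g,
    λ_g(u) = r_g λ*(u),   S_g(u+1) = S_g(u)(1 − λ_g(u)),

which satisfies the survivor-weighted constraint *exactly* at every age
(to 1e−12 in the property tests); a fixed-point loop would add nothing on
a discrete grid. Odds ratios are used as relative risks, valid while
annual risks are small (the recursion raises if any calibrated annual
hazard reaches 1). Survivor weighting (rather than static population
fractions) is what makes whole-population risk conservation exact.
Lifetime risk is reported to age 80. Cumulative risks over [a, b)
renormalise both survival functions to 1 at age *a*, i.e. they are
conditional on being alive and disease-free at *a*.

Screening analytics build a 0.1%-wide centile grid with normal-shift
relative risks `r_g = (Φ(q_hi − γ) − Φ(q_lo − γ)) / f_g` (mean-1 by
construction), flag a centile eligible when its maximum 10-year risk over
ages 20–70 reaches the threshold (default 2.3%), and weight captured cases
by each centile's share of calibrated incidence. A life-history
microsimulation of the same multiplicative model reproduces the captured
fraction within ±0.02.

## Effect-size concordance (EM-ICC)

Observed per-SNP log ORs obey y_ij = β_ij + δ_ij with known sampling SDs
σ_ij, and β_ij ~ N(α_i, σ_R²) around a per-SNP mean. The SNP means are
modelled as α_i = μ + a_i with a_i ~ N(0, σ_A²). The EM E-step shrinks each
estimate toward its SNP mean with precision weights — β̂_ij is the weighted
mean of y_ij and α_i with weights 1/σ_ij² and 1/σ_R² — and the M-step
updates (μ, σ_A², σ_R²) from posterior moments. Convergence is declared
when the ICC = σ_A²/(σ_A² + σ_R²) changes by < 1e−8 (1,000 iterations
cap; near a variance boundary the approach is asymptotic and the cap can
be reached with the ICC already stable to several decimals).

Two design points were genuinely open and are resolved as follows:

* **Random rather than fixed SNP means.** Treating the α_i as free per-SNP
  parameters has two failure modes, both verified numerically: the sample
  variance of the fitted means retains their sampling noise, so the ICC
  cannot approach 0 when all SNPs truly share one effect; and with only
  two or three populations per SNP the residual-variance MLE is
  inconsistent (a Neyman–Scott problem) and collapses to the zero boundary
  whenever the known noise exceeds half the within-SNP spread. The
  random-effects formulation has neither problem, agrees with a direct
  numerical maximisation of the marginal likelihood to four decimals, and
  recovers generating ICCs within ±0.05.
* **Posterior-variance augmentation.** An M-step that treats the shrunken
  values as exact complete data contracts both variances every iteration
  and collapses toward zero; it is kept as `m_step="plugin"` purely to
  document the degeneracy, and a test asserts the collapse.

σ_R² is pooled across SNPs (one residual variance), matching the single
shrinkage weight in the E-step. SNPs missing in some populations (e.g.
monomorphic ones) are handled pairwise-complete. The iteration
standardises the inputs internally so results are exactly equivariant
under rescaling all y and σ by a constant.

## Synthetic-data generator

The generator emulates the *statistical structure* of a two-population PRS
transfer study; its defaults are the study conditions downstream tests
assume.

* **Weight panel** (default 313 SNPs, 26 with INFO < 0.9): independent
  SNPs, population-1 allele frequencies uniform on [0.10, 0.50]; a
  configurable fraction (default 43/287 ≈ 0.15) of SNPs is rare
  (MAF < 0.05) in population 2, the paper-scale mechanism by which the
  second population's PRS SD is lower. Weights are Gaussian, scaled so
  the population-2 PRS SD equals its target (0.556) exactly; the
  population-1 SD is emergent from the frequency spectrum and lands near
  its 0.597 reference value. One shared weight vector cannot hit two SD
  targets independently, so the analysed population is the one pinned.
* **Case–control cohorts** (default 15,755 / 16,483 in 10 strata):
  dosages are Binomial(2, freq) with no LD — the downstream theory treats
  SNPs as independent, and LD matters only for weight derivation, which
  is out of scope. Disease is sampled by rejection from a synthetic
  population with logit P(case) linear in the raw PRS at baseline
  prevalence 0.05 (configurable; published case–control sampling implies
  no particular value, so it is a parameter, and the slope per raw unit
  is `per_sd_log_or / reference_sd` so recovered per-SD ORs are
  insensitive to it). Ten standard-normal principal components, strata,
  ages, ethnicity labels, and ER subtype (66% ER-positive among the 97%
  of cases subtyped, independent of the PRS by default) are attached.
* **Family history**: one simulated first-degree relative per woman, PRS
  correlation 0.5, disease risk log-linear in the relative's own PRS at
  marginal prevalence 0.10. Family history is therefore informative about
  case status *only through the PRS*; adjusting for the PRS attenuates
  the FH log-OR essentially fully. Real family-history effects are much
  larger and mostly not PRS-mediated, so the generator supports sign and
  attenuation-direction checks, not Table-style attenuation percentages.
* **Prospective cohort** (default 10,255 women): entry ages uniform on
  43–75, constant baseline hazard times exp(β·PRS), exponential dropout
  plus an administrative follow-up limit (19 years). A helper solves the
  baseline hazard for a target expected event count (≈413 events in the
  default configuration) from the closed-form event probability averaged
  over the PRS distribution.
* **Rates tables**: Gaussian-bump incidence peaking between ages 40 and
  50 (peak 1.9 per 1,000 person-years, the scale of Singaporean
  registry incidence) and Gompertz competing mortality
  (2e−5 · exp(0.095·age)). These are synthetic stand-ins: real
  ethnicity-specific registry rates are inputs the reader supplies, so
  published absolute-risk tables are not reproduction targets.
* **Effect panels**: per-SNP means N(0, 0.08²) — the spread of per-allele
  log ORs in a PRS of this size — population deviations N(0, within_sd²)
  (default 0.02; 0 is the shared-architecture mode), and known SEs
  uniform on [0.03, 0.15], the scale of GWAS with a few thousand cases.

All generators draw from one seeded PCG64 stream per dataset
(`(seed, stream-tag)`), so identical configurations give byte-identical
outputs and every dataset records its ground truth.

**What passing tests show — and don't.** Parameter recovery on these
cohorts validates the estimators under the generating model: independent
SNPs, exactly logistic disease risk, normal covariates, non-differential
ER subtyping, no LD, no genotyping error, no population stratification
beyond labelled strata. Real-data complications (LD between panel SNPs,
imputation error correlated with frequency, ancestry-confounded PCs,
family-history misreport) are deliberately outside the generator, so
green tests certify the arithmetic and the statistical machinery, not
robustness to those complications.

## Problem sizes used by the test suite

Unit tests run on small cohorts (hundreds to a few thousand individuals,
25–100 SNPs). The headline checks use the published design sizes where
that is the point (15,755/16,483 case–control replicates for per-SD OR
recovery; 10,255-woman prospective cohorts), 313-SNP panels for the
filtering counts, 10⁷ draws for the Monte-Carlo bin-OR oracle, 10⁶ life
histories for the screening microsimulation, and 287-SNP effect panels
for the ICC checks — sizes chosen so each check has comfortably more
precision than the tolerance it asserts.

## Known limitations

* ORs are treated as RRs in the absolute-risk calibration; fine at annual
  risks ≪ 1, increasingly wrong for very high-risk groups or very high
  incidence.
* The normal-shift bin predictions assume a normally distributed PRS;
  scores dominated by a few large-effect, low-frequency variants would
  deviate in the extreme percentiles.
* The study-adjusted AUC definition is one defensible reading of
  "adjusted by study"; alternative covariate-adjusted ROC estimators give
  slightly different values.
* The EM-ICC pools a single σ_R² across SNPs; a per-SNP residual variance
  is not identifiable with two or three populations.
* The pipeline's CLI writes plain-text outputs only (TSV/CSV/JSON/VCF);
  there is no plotting.
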