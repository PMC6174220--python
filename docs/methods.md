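# Methods

## Model and measures

The package works with a binary disease outcome Y and per-variant allele
counts X_k ∈ {0,1,2} assumed to be in Hardy–Weinberg equilibrium at population
risk-allele frequency p_k. Effects are multiplicative on risk (log-linear) or
on odds (logistic); the per-allele relative risk is e^β. The population
attributable fraction is Levin's: PAF = (P(Y=1) − P(Y=1|X=0)) / P(Y=1), the
proportional drop in disease risk if every risk allele were replaced by its
complement, all else unchanged. For the closed forms used, see the README; the
joint PAF is always evaluated by exact enumeration of the 3^K genotype support
(refused above K = 15, where 3^K enumeration stops being sensible — the
Monte-Carlo path has no such cap in principle but is quadratic-to-cubic in K
through the copula solve and the logistic fit).

Protective alleles (OR < 1) are always re-oriented to the complementary allele
(frequency 1−p, reciprocal OR, reciprocally swapped CI) before a PAF is
computed. This keeps PAF in [0,1) and matches how published protective
variants are handled; the orientation function is idempotent.

Dominant and recessive codings replace the additive genotype-class relative
risks (1, RR, RR²) by (1, RR, RR) and (1, 1, RR).

## PAF ↔ heritability

For a binary trait, `PAF ≈ h·CV_Y/CV_Xβ`. CV_Y = √((1−P_Y)/P_Y) is exact for a
Bernoulli trait. CV_Xβ is the coefficient of variation of the genotype linear
predictor, enumerated exactly over the genotype distribution. The identity
comes from a quadratic Taylor expansion of the risk model in the genotype
count: the expansion design is (Z, Z²) with coefficients (δ, δ²/2) under a log
link and (δ, (1−e^{δ0})/(2(1+e^{δ0}))·δ²) under a logit link with baseline
log-odds δ0; below a baseline risk of 0.01 the logit expansion is collapsed to
the log form (the two agree to first order in the baseline odds).

Two deliberate choices:

* The tabulated statistic h* = h·CV_Y/CV_Xβ uses the **linear-term-only** CV
  (CV of δZ). The quadratic CV is available via the expansion flag, but the
  linear CV is the convention the simulation studies and the worked examples
  adopt; for a single variant the linear CV is δ-free (sd(Z)/mean(Z)), which
  makes h* a pure function of (h², P_Y, p).
* h² "from data" is the coefficient of determination of an ordinary
  least-squares fit of Y on the expanded design (Z_k, Z_k²) — for one variant
  that design saturates the three genotype classes, so the population value is
  Var(E[Y|Z])/Var(Y).

The identity is an approximation: mapping a PAF through it does not exactly
reproduce the regression R² (the gap grows with the effect size; ~1% relative
at β = 0.2, ~4–15% at β = 0.3 depending on the design used). The
`h2_observed`/`h_star_from_h2` pair is exactly self-inverse by construction,
and a test checks the Monte-Carlo consistency of the identity value with the
simulated regression R² at the 10% level.

Liability-scale conversion uses the threshold model: h²_L = c·h² with
c = P_Y(1−P_Y)/υ², υ the standard-normal density at Φ⁻¹(1−P_Y). c is symmetric
in P_Y ↔ 1−P_Y and equals π/2 at P_Y = 0.5.

## Correlated binary and genotype generation

Correlated Bernoulli vectors are produced by dichotomising a latent
multivariate normal: coordinate j is 1 when Z_j > Φ⁻¹(1−p_j). For each pair,
the latent correlation is found by Brent root-finding on the bivariate-normal
orthant probability so the dichotomised pair hits the target Pearson
correlation on the binary scale (|Δ| < 1e-10 in the joint success
probability); targets at the Fréchet bounds map to latent ρ = ±1, which attain
them exactly. Targets are validated against the Fréchet feasibility range
implied by the two marginals. Pairwise solutions are assembled into one latent
matrix; if it is not positive semi-definite it is repaired by eigenvalue
clipping (rescaled to unit diagonal) with a warning. Sampling uses the
symmetric eigendecomposition square root, which handles singular (perfectly
correlated) cases exactly, and a single user-seeded NumPy generator feeds
every stochastic step of a pipeline run.

Genotypes are sums of two exchangeable latent allele indicators with success
probability p_k. The two alleles of one variant are kept independent, which
enforces Hardy–Weinberg proportions by construction. Correlation targets are
translated to the allele level as:

* trait–genotype correlation c_k → allele–trait correlation c_k/√2,
* genotype–genotype correlation r_jk → correlation r_jk/2 between **every**
  cross-variant allele pair (four pairs).

Both translations follow from Var(X) = 2p(1−p) and the bilinearity of
covariance. The exchangeable four-pair coupling reproduces the same
genotype-scale correlation as a haplotype-style coupling (only cis allele
pairs correlated at r) but is always feasible whenever |r/2| is; it does not
model phase, which the PAF computation never needs. LD is supplied as r² and
converted as r = +√(r²); r² is signless, and the positive sign is the relevant
case when both reported risk alleles have OR > 1 (a sign override is
available).

## Joint effects and PAF from summary statistics

1. **Implied correlations.** Each variant's log-OR and standard error give a
   signed score statistic ST = β̂/sê and the implied correlation
   Corr(Y, X_k) ≈ ST_k/√N_k, using each variant's own study size. The standard
   error comes from the reported 95% CI, sê = (log U − log L)/(2·1.96); a
   p-value is used only as a fallback (or a consistency check when both are
   present, warning at >20% disagreement).
2. **Joint refit.** A synthetic sample (default 100,000) of (Y, X₁..X_K) is
   drawn with those trait–genotype correlations, the LD-implied
   genotype–genotype correlations, HWE marginals at the reported RAFs, and
   Y-marginal equal to the case fraction of the analysed samples (averaged
   across studies when the variants come from different studies — the score
   statistic's ȳ is the analysed sample's case fraction, not the population
   prevalence). One multivariate logistic regression on this sample gives the
   joint per-allele log-ORs. The fit is aggregated over the 3^K genotype
   cells, making its cost independent of the simulation size.
3. **Population distribution.** A second draw using the RAFs and LD only
   (no Y) provides the empirical population genotype distribution; for a rare
   disease the controls' frequencies stand in for the population.
4. **PAF.** Enumerate the joint PAF formula over that distribution with the
   joint effects, optionally converting each joint OR to an RR first via
   RR = OR/(1−P₀+OR·P₀) when a baseline risk is supplied (the correction
   always shrinks toward 1; it is exact for a binary exposure and approximate
   per allele).
5. **Bootstrap.** Each replicate redraws every marginal log-OR independently
   from N(β̂, sê²) (no cross-variant covariance is recoverable from summary
   statistics), recomputes the implied correlations, and reruns steps 2–4
   including the population draw, so simulation noise is part of the
   replicate-to-replicate variation. The 95% CI is the point estimate
   ± 1.96·sd(bootstrap PAFs), truncated to [0,1]. Defaults: 100,000
   Monte-Carlo samples, 1,000 bootstrap replicates.

For a single variant the estimator is closed-form (plug the — optionally
corrected — OR into the three-genotype formula; bootstrap by redrawing the
log-OR), and the Monte-Carlo path reduces to it up to simulation noise; a
bootstrap draw that crosses the null is floored at PAF 0.

**A consistency caveat that matters in practice.** The pipeline's round trip
(β̂ → correlation → simulate → refit) is exact only when the reported standard
error is consistent with the score-statistic standard error implied by N and
the case fraction. Published CIs from covariate-adjusted or multi-stage
analyses can be tighter than that, which inflates the implied correlation and
hence the refit effects. For the bundled lung-cancer variants the printed CIs
are consistent with the *combined* two-stage sample sizes, so those are the
study sizes the fixtures carry.

## Simulation studies

Cohort studies draw N = 100,000 individuals: genotypes binomial(2, p) (or via
the copula generator when a genotype correlation is requested), disease from
P(Y=1|X) = b·exp(Σβ_k X_k) (log link; the model validates b·max RR ≤ 1 before
sampling) or expit(δ0 + Σδ_k X_k) (logit link). Default baseline risks: 0.10
for the log-linear studies (a disease incidence around 10%) and 0.05 for the
logistic ones (rare enough that the OR approximates the RR). Each replicate
fits the link-appropriate binomial GLM (log-link fits are started from the
weighted least-squares solution on log cell means for stability), then
evaluates the plug-in PAF from fitted effects and fitted allele frequencies
— without the orientation guard, so null effects average to zero — plus h*
and the regression h². True values are computed by enumeration (correlated
genotype distributions use a fixed-seed draw of 10⁶ genotypes, since the
dichotomised-normal joint pmf has no closed form).

Case-control studies nest the standard design in such a cohort: all cases plus
an equal number of random controls, a separate marginal logistic fit per
allele (OR, 95% CI — the typical GWAS output), population RAF estimated from
the controls, then the summary-statistics estimator with and without the
OR→RR correction, scoring relative bias and bootstrap-CI coverage against the
cohort truth. The "very rare" and "relatively common" event-rate bands are
positioned by baseline risks 0.02 and 0.08 (both configurable; the bands are
defined by the resulting event rates, <5% and 5–10%). The h² recorded per
replicate is the identity value at the corrected-OR PAF.

Replicate counts are configurable everywhere; the bundled tables default to
1,000 replicates (500 bootstrap-heavy case-control cells use 500/200), while
the test suite and the acceptance script run 40–150 replicates — enough that
the Monte-Carlo standard error of each checked mean is a few per mil — and
compare means at three Monte-Carlo standard errors. The acceptance script uses
150 cohorts (single variant), 120 cohorts (trio), and one pipeline run at
100,000 Monte-Carlo samples for the correlated pair.

## What the generators do and do not emulate

The synthetic data reproduce the features the estimators rely on: HWE
marginals, pairwise trait–genotype and genotype–genotype Pearson correlations,
case-control sampling, and normally distributed log-OR estimates. They do not
model haplotype phase, higher-order LD, covariates or population
stratification, genotyping error, or winner's-curse selection of reported
variants. Passing tests therefore demonstrate internal correctness of the
estimators under their own assumptions, not robustness to those real-data
complications; in particular, covariate-adjusted published ORs are taken
as-is.

## Known limitations

* The OR→RR correction is exact for a binary exposure but approximate per
  allele; residual bias grows with the OR and the baseline risk.
* The PAF↔h² identity is a Taylor approximation; for large effects PAF is
  systematically slightly smaller than h*.
* The liability transform needs the true prevalence; for rare diseases the
  scale factor c is large (≈43 at prevalence 0.0024), so h²_L inherits any
  prevalence misspecification multiplicatively.
* Bootstrap CIs are normal-approximation (mean ± 1.96·sd of the replicates),
  chosen over percentile intervals to match the estimator's construction from
  a standard deviation; they can nominally cross 0 or 1 and are truncated.
* PAF quantifies attribution under the model, not causality: a tag variant in
  LD with the causal one attenuates both PAF and h².
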