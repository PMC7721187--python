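# Methods

`duopgs` analyses the genetic architecture of the tails of the birth weight
distribution: how much of being born small- or large-for-gestational-age
(SGA/LGA) is explained by the common-variant polygenic scores of the baby
and of the mother, and whether babies at the extremes deviate from what an
additive polygenic model predicts. Real mother–child cohorts with genotypes
and birth records are access-restricted, so the package ships a synthetic
duo generator with the statistical structure the analysis assumes and runs
the full analysis against it; external weight tables and dosage data can be
substituted at every entry point.

## Generative model

For a panel of `m` independent biallelic SNPs with effect-allele
frequencies `f_i`, maternal genotypes are drawn Binomial(2, `f_i`)
(Hardy–Weinberg); the child receives one maternal allele chosen uniformly
from the mother's two, plus a paternal allele Bernoulli(`f_i`). The father
is never materialized. Under random mating this yields the classic duo
dosage correlation of 0.5, the quantity that confounds maternal and fetal
marginal GWAS estimates.

The standardized phenotype is additive in both genomes:

    bw_z = Σ_i βF_i (g_child,i − 2 f_i) + Σ_i βM_i (g_mother,i − 2 f_i) + ε

with `ε ~ N(0, σ²)`. By default `σ²` is chosen so Var(bw_z) = 1, which
requires the cross term: because cov(g_child, g_mother) = f(1−f), the
genetic variance is `Σ 2 f_i (1−f_i) (βF_i² + βM_i² + βF_i βM_i)`.
Gram-scale birth weight is `3500 + 500·bw_z` g — plausible term magnitudes,
configurable, and irrelevant to any inference because every analysis is
rank- or z-based. Sex is Bernoulli(0.5) and gestational age
discrete-uniform on 37–42 completed weeks: the package models **term
singletons only**, and all analyses filter GA ≥ 37 first.

Effect sizes are bivariate normal across SNPs with a configurable
maternal–fetal correlation. The helper `effect_sd_for_variance` picks the
per-SNP effect SD so a panel explains a target share of phenotype variance;
the working default emulates a genome-wide-significant panel explaining 7%.

Two *contamination* modes deliberately violate the additive model, on the z
scale so the injected deficit has SD units: an environmental deficit
(`shift_sd` subtracted from a random fraction of babies) and a rare
un-scored large-effect allele (carriers at `rare_freq` lose `rare_beta` per
allele). The generator does **not** model linkage disequilibrium,
assortative mating, imputation uncertainty, X-linked loci, multiple births
or preterm delivery — so a passing suite says the *methods* behave as
designed under the assumed sampling model, not that real cohorts satisfy
that model.

## Genetic scores

The score of an individual with dosages `g_i` and per-allele weights `w_i`
over `N` scored SNPs is

    GS = N · (Σ_i w_i g_i) / (Σ_i w_i),

a weighted allele count normalized so equal weights reduce it exactly to
the raw allele count. The denominator is only meaningful when the weights
share a sign, so variants are oriented to the score-raising allele: the
weight-table reader flips rows with a negative fetal (or single) weight
(alleles swapped, weights negated, frequency complemented), and
`compute_gs` flips any residual negative-weight variant per score role
(`g → 2 − g`, `w → −w`). A maternal/fetal weight pair with opposite signs
at one variant cannot be oriented once for both scores, which is why the
per-role flip exists. Missing dosages are dropped per individual from
numerator, denominator and the `N` factor — preserving the score's scale
under sporadic missingness — and individuals missing >5% of the panel are
flagged. Absolute score units are convention-dependent; inference uses
within-cohort deciles (rank blocks of near-equal size, stable ties), which
are invariant to the scale.

Marginal child and mother GWAS estimates mix direct fetal and indirect
maternal effects through the 0.5 duo correlation:
E[β̂_child] = βF + βM/2 and E[β̂_mother] = βM + βF/2. `wlm_adjust` inverts
this system exactly (βF = (4β̂_child − 2β̂_mother)/3 and symmetrically),
the weighted-linear-model separation used to form independent maternal and
fetal score weights. Standard-error propagation into adjusted weights is
out of scope.

## Phenotype classification

Z-scores come either from an external sex × gestational-week growth
reference (mean/SD rows, or LMS rows with `z = ((bw/M)^L − 1)/(L·S)`,
`L = 0` handled as `ln(bw/M)/S`) or from the within-cohort route: OLS of
birth weight on a sex indicator and linear gestational age among term
births, residuals divided by the residual SD (a quadratic-GA flag exists;
the linear form is the default reading). The primary case definition is
z ≤ −1.28 (SGA) and z ≥ +1.28 (LGA), boundaries inclusive — the ~10th and
~90th normal centiles. Sensitivity definitions take the lowest/highest 10%
of within-cohort z (floor(n/10) each, ties broken by individual ID), and
controls are either all non-cases per outcome or only
appropriate-for-gestational-age babies between the cut-offs.

## Association and meta-analysis

Case–control models are maximum-likelihood logistic regressions with the
decile (1–10) entered as a continuous exposure, so effects are "per 1
decile higher GS"; Wald standard errors, 95% CIs and p values. Joint models
put both duo scores (or a maternal exposure score plus the fetal score,
with sex and GA covariates) in one design. Complete separation raises an
error; quasi-separation and dropped constant covariates are flagged. A
linear-probability flag exists for sensitivity only. Cohorts are pooled by
fixed-effect inverse-variance weighting, with Cochran's Q (df = k−1) for
heterogeneity, flagged at q_p < 0.05. Random-effects pooling is out of
scope.

## Deviation from the additive polygenic model

The test asks whether the mean score of babies in each bin of the
birth-weight distribution matches an additive polygenic model. Per SNP, the
*conditional* effect of one duo member is estimated by OLS of bw_z on that
member's dosage adjusted for the other member's dosage at the same variant
(with its Wald SE); the variance explained is `σ²_SNP_i = 2 f (1−f) β²`
(HWE, unit phenotype variance). The null model writes the standardized
phenotype as `p_s = x_s + GS_s` with `GS_s = Σ β_i (g_i − 2 f_i)`,
genotypes Binomial(2, f̂) at the observed frequencies, and
`x_s ~ N(0, 1 − Σ σ²_SNP_i)` — the second argument read as a **variance**,
so `p_s` has unit variance. Both observed and simulated scores are
standardized before their bin means are compared, making results invariant
to score scale. 10,000 null replicates by default (tests and studies use
500–1,000 for runtime).

How each null replicate is *scored* matters. The observed statistic uses
weights estimated from the analysed sample, and its in-sample
score–phenotype association carries that estimation noise. Scoring
replicates with the fixed observed estimates treats those noisy values as
true effects, which makes the null's score–phenotype relation
systematically steeper than the observed one — an anticonservative bias of
order m/(3n) in the score–phenotype covariance (the factor arising from
the conditional adjustment at duo correlation ½), clearly measurable when
the panel size m is not small relative to the cohort n, and in the same
direction as a genuine tail deficit. The default null is therefore the
parametric-bootstrap form: each replicate simulates a full mother–child
duo, generates the phenotype with *noise-debiased* weights (a global
shrinkage using the conditional SEs, since E[β̂²] = β² + se², so the
simulated panel explains the estimated rather than the noise-inflated
share of variance), re-estimates the conditional per-SNP weights from its
own data exactly as the observed pipeline does, and scores itself with
those. Calibration studies confirm near-nominal type-I error for the
bootstrap form and measurable inflation for the fixed-weight form;
`reestimate=False` retains the simpler fixed-weight variant. The price of
the calibrated null is honest: part of an injected tail anomaly is
absorbed into the attenuated in-sample weight estimates, so power against
tail contamination is modest at desk-scale panels.

Numerical choices: genotype sampling uses 16-bit inverse-CDF lookups (cell
probabilities quantized to 2⁻¹⁶, far below Monte-Carlo noise) and the
genotype block runs in float32, chunked to bound memory; bin edges are
quantile ranks with deterministic ID tie-breaks; bins can be anchored at
the bottom (0–3, 3–6, …) or the top (…, 94–97, 97–100) of the
distribution, since tail labels at both ends are conventional — both are
available and neither is asserted as canonical.

The empirical p is two-sided by default with the add-one correction,
`p = min(1, 2(min(a,b)+1)/(S+1))` where `a`/`b` count null values
below/above the observed mean, because deviations are interpretable in both
directions and the 95% envelope drawn is two-sided; a one-sided flag
exists. Per-cohort p values are combined by Stouffer's method with √n
weights and a sign from (observed − null mean); the combination method for
empirical p values is genuinely open, and this choice is ours.

A deficit of genetic smallness among the smallest babies — growth
restriction by environment or by rare un-scored variants, the two being
indistinguishable here — appears as an observed bin mean *above* the null
envelope in the lowest bins.

### Calibration and power studies

`validation.calibration_study` measures the lowest-bin rejection rate at
nominal 0.05 on datasets generated with **fetal effects only**. This is
deliberate: the null model writes the phenotype as the scored member's GS
plus independent noise, and a correlated contribution from the unscored
parent violates that model by construction and genuinely shifts tail bin
means — it is a detectable model violation, not a calibration condition.
The study uses 200 datasets of 2,000 duos, a 50-SNP panel explaining 7% of
variance, and 500 null replicates; residual anticonservatism from
estimating β̂ and f̂ on the analysed sample is expected to be small at
these sizes.

`validation.power_study` injects an environmental deficit (default 1.5 SD
in 1%, 3% or 10% of 5,000 babies, 1,000 null replicates, 40 dataset
replicates) and reports the detection rate (two-sided p ≤ 0.05 in the
lowest 3% bin) and the direction rate (observed above null). The three
contamination arms share a base cohort per replicate with *nested*
contaminated sets — common random numbers — which leaves each arm's
marginal distribution untouched while sharpening the monotone
dose–response comparison.

## Pipeline and reproducibility

`run_pipeline` chains simulate → z-score → score → classify → associate →
deviation-test for a list of cohorts (simulated, or read from dosage TSVs
or a VCF's DS field with allele harmonisation: orientation swaps map
`g → 2 − g`, strand-ambiguous A/T and C/G variants are dropped, and a run
aborts if fewer than half the panel's SNPs are found). All randomness flows
from the single config seed through named substreams; every output TSV
carries the seed and a config hash, and the manifest records counts at each
filter, so a rerun with the same config is byte-identical.

## Known limitations

Scores here are built from user-supplied or simulated weights; the package
neither runs a GWAS nor re-derives published weight tables, and growth
reference values are user-supplied. The deviation test inherits the
approximation of plugging in-sample conditional estimates into its own
null; simulation sizes below ~1,000 replicates limit the resolution of
small empirical p values to `2/(S+1)`. Conclusions about real cohorts
require real cohort data.
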