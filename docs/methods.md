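# Methods

This note records the models implemented, the defaults and why they
were chosen, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions that matter for reproducing the
outputs.

## Ancestry assignment

A participant's genetic ancestry is summarised upstream (outside this
package) as proportions over the five superpopulations; here only the
thresholding is performed. The comparison is inclusive (≥ 0.8), so a
participant at exactly the threshold is assigned. With proportions
summing to one and a threshold above 0.5 at most one component can
qualify; the impossible exact tie is still guarded and raises rather
than tie-breaking silently. Self-reported ethnicity concordance
excludes participants with a missing self-report from the denominator
by default (configurable), since a missing category is not evidence of
discordance.

## Clinical regression battery

All models take ancestry as an unordered factor with EUR as reference
and use complete-case rows per outcome; no imputation is performed.
Confidence intervals are 95% Wald throughout, matching the forest-plot
reporting style.

- **Ages** (years): OLS. With a factor-only design the coefficients
  are exactly the group-mean differences, which the tests exploit as a
  closed-form oracle.
- **Categorical outcomes**: logistic regression on a dichotomised
  outcome. Receptor statuses code the negative state as the event
  (positive = reference). Ordinal grade/stage code the upper levels as
  the event; if the upper cell would hold fewer than five
  observations, adjacent upper levels are merged downward until it
  does. Deprivation is coded as the two most deprived quintiles. A
  level whose outcome is constant is flagged non-converged and left
  out of the fit instead of poisoning it with a divergent coefficient.
- **TMB**: negative-binomial (NB2) regression of retained mutation
  counts with log(exome Mb) as exposure, so exponentiated coefficients
  are per-Mb rate ratios. With a shared exome size the offset only
  moves the intercept; a no-offset variant exists behind a switch for
  data with per-sample exome sizes. On Poisson-distributed counts the
  NB fit collapses to the Poisson estimates (tested to 1e-3).
- **Deprivation tests**: the nested LRT compares `outcome ~ ancestry`
  against `outcome ~ ancestry + IMD` on the same rows, IMD entering as
  an unordered factor (4 d.f. when all five quintiles occur). A
  constant IMD column yields an explicit no-test flag, not a p-value.
  Within-group association tests use one-way ANOVA for numeric
  variables (group means reported for direction) and chi-square for
  categorical ones, switching to Fisher's exact test for 2x2 tables
  with an expected cell below one (flagged).

## Somatic retention and TMB

The decision tree evaluates eligibility (non-synonymous, exonic)
before any frequency logic. Boundary comparisons follow the stated
operators exactly: ≤ 0.1% gnomAD, ≥ 3% VAF, ≥ 2 COSMIC identifiers,
≤ 10% for the COSMIC-rescued common band, > 0.1% TOPMED for the
override. The upper bound of the common band is read as 10% (a
fraction of 0.10); no VAF condition applies in that band. A frequency
absent from gnomAD or TOPMED is treated as 0 — the variant was not
observed in the reference panel, the standard convention. The TOPMED
exclusion is applied after the retention rules as an override. The
tests hold the implementation to a brute-force truth-table oracle over
every band combination.

TMB = retained count / exome Mb with a default exome of 35.4 Mb.

## Differential mutation

The per-feature logistic model adjusts for age at diagnosis and is
fitted only where estimable: a feature with zero or universal carriage
in any ancestry group would separate, so it is flagged and handled by
the threshold route. Quasi-separation that survives the pre-check is
caught by the iteration cap and a runaway-coefficient guard (|β| > 15).
BH adjustment runs across features within each ancestry contrast, and
separately per feature kind (genes and variants are distinct
families); Bonferroni is available behind a flag. Significance is
adjusted p < 0.1.

The presence threshold is strict: a feature is present when its
carrier count exceeds 2% of the cohort, i.e. count ≥ ⌊0.02 n⌋ + 1,
computed in exact rational arithmetic to avoid float artefacts at
integer multiples of the threshold. Present features fall into exactly
one of the seven non-empty intersection sets; the single-minority sets
are the headline outputs.

## Germline filtering and enrichment

The panel is the de-duplicated union of the supplied gene lists
(180 genes by default in the synthetic panel). Confident-pathogenic
requires ClinVar pathogenic/likely pathogenic at ≥ 2 review stars on
the canonical transcript of a panel gene. VUS carries no star
requirement: the star rule expresses confidence in a *pathogenic*
assertion, and an uncertain call is uncertain at any review depth.
Per-participant burden means count variants (not distinct genes) and
include zero-carrier participants in the denominator. For enrichment,
multiple qualifying variants in one gene collapse to a single carrier
flag (standard burden coding); a per-variant mode exists. X-linked
genes can be excluded behind a flag to mirror call sets without
chromosome-X coverage in case/control mode. The Fisher test reports
the two-sided p by hypergeometric summation and the conditional MLE
odds ratio.

## Power analysis

The design fixes the minority-group mutation frequency and back-solves
the reference frequency from the odds ratio under test, so "frequency"
always refers to the minority group. For a single binary covariate the
logistic MLE equals the sample log odds ratio of the 2x2 table and its
Wald SE is √(1/a+1/b+1/c+1/d); the simulation therefore draws the two
binomial carrier counts directly — that *is* the per-feature model fit,
and the tests verify the identity against a full statsmodels fit.

Two conventions are implemented. The default is the two-sided Fisher
exact test at α = 0.1: the significance rule of the differential
analysis operates at adjusted p < 0.1, and at the study-scale designs
(2,343 vs 123/138, 5–25% minority frequency) exact power calculations
show that this convention places detectable odds ratios in the 2–6
range at 90% power, consistent across all three designs, whereas a
5% level would demand noticeably larger effects than the differential
analysis actually flags. The Wald convention (matching the per-feature
inference) is available via `PowerDesign(test="wald")`; at these cell
counts it is slightly anti-conservative relative to Fisher, shifting
detectable ORs down by roughly 0.2–0.3. A table with an empty cell is
non-estimable under the Wald convention and counts as a non-rejection.

`detectable_or` scans a geometric grid for an upper bracket before
bisecting, because power is not monotone out to extreme odds ratios:
the back-solved reference frequency shrinks toward zero and the tables
degenerate. Bisection stops at a bracket width of 0.01. A
deterministic enumeration route (`method="exact"`) sums the joint
binomial mass over the rejection region and serves as the oracle for
the simulation; a closed-form normal approximation is also provided
and agrees with the enumeration within 0.05 at the study-scale
designs.

## Synthetic-cohort generator

The generator emulates a harmonised analytic cohort at the
called-variant level; it does not simulate reads, alignment or variant
calling, and annotation columns are drawn from parametric
distributions rather than real database lookups.

Defaults are the study conditions the analyses are designed around:
group sizes 2,343/138/123/177 (EUR/AFR/SAS/Admix), age at diagnosis
truncated-normal on [18, 100] years with EUR mean 62.5 and per-group
SDs of 13–15 chosen so the central-60% bands land near 50–75 (EUR),
47–69 (AFR) and 45–68 (SAS) after the injected shifts (−5.28 years
AFR, −6.91 SAS); ER/PR negativity odds ratios of ~2.06/2.07 in AFR on
EUR base rates of 15%/25%; grade-3 OR 1.88 in AFR; a deprivation
gradient toward the more deprived quintiles in AFR/SAS; an EUR
retained-mutation mean of 53 (TMB ≈ 1.5/Mb over 35.4 Mb) with NB2
dispersion 0.4 and multiplicative group effects (0.845 in SAS);
germline carrier rates for BRCA1/BRCA2/PALB2 elevated in the minority
groups with VUS intensities near 19.5 (EUR) to 21.2 (AFR) calls per
participant. Where no study condition pins a marginal (stage,
lymph-node, HER2 distributions), the defaults are labelled
placeholders in the config and sit at plausible clinical magnitudes.

Ancestry proportions are Dirichlet draws with the intended label's
concentration calibrated (by solving the Beta marginal) so the ≥ 0.8
rule reproduces the intended label for 95% of non-admixed participants
by default; the remainder present as Admix, which is what real
threshold labelling does to borderline individuals. Driver somatic
variants are recurrent, COSMIC-annotated, gnomAD-absent and clonal, so
they survive the retention filter deterministically and injected gene
frequencies are recoverable downstream; passenger variants drive TMB,
with Zipf-weighted gene usage so per-gene frequencies span the 2%
presence boundary, and the pre-filter intensity is scaled by the
analytic retention probability of the annotation model so the
post-filter mean hits the configured TMB level. Binomial thinning of
the gamma–Poisson passenger process keeps the NB family, which is why
`generate_retained_counts` can draw post-filter counts directly for
regression-recovery studies. All randomness flows from one seed
through named sub-streams, so the clinical table is bit-identical
whether or not variant tables are generated.

What passing tests show: the estimators recover the effects the
generator injects, at the configured sizes, under correctly specified
models. What they do not show: robustness to the ways real cohort data
violate the generator — informative missingness, miscalibrated
upstream ancestry proportions, population substructure within labels,
annotation errors, or confounding structures other than the ones
injected.

## Problem sizes

Unit tests run on cohorts of 150–800 participants per group; the
parameter-recovery acceptance battery uses 100 replicates at 2,000 per
group for the linear/logistic/NB/per-feature models; power checks use
the deterministic enumeration plus 20,000–50,000 simulation draws.
These sizes give the tests stable verdicts while keeping the full
suite in the minutes range on one CPU.

## Known limitations

- The threshold route and the logistic route partition features by an
  estimability check, not by a formal model-selection rule; features
  near separation can be estimable yet unstable, which the
  runaway-coefficient guard only partially addresses.
- The NB "rate" alternative (no offset) is indistinguishable from the
  offset form when every sample shares one exome size; it exists for
  per-sample exome sizes but is untested against real capture kits.
- The generator's annotation model draws population frequencies from a
  shared log-uniform base with lognormal jitter; real gnomAD
  frequencies are far more structured across populations.
- Fisher-convention power uses the conservative exact test; true size
  sits below α at these cell counts, so reported detectable ORs are
  slightly conservative relative to an unconditional test.
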