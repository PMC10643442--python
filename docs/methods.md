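# Methods

`dyadmr` implements a dyadic (cross-partner) one-sample Mendelian
randomisation workflow for couple cohorts, together with the synthetic
couple generator used to validate it.  This note documents the models,
the defaults and the numerical choices.

## The identification problem

A cross-spouse phenotypic correlation r(X_f, X_m) is compatible with
three mechanisms:

1. **Assortative mating** — partners are selected on phenotypic
   similarity.  Because the phenotype is partly heritable, mate choice
   induces a cross-spouse *genotype* correlation.
2. **Partner interaction** — partners causally influence each other's
   phenotype after pairing.  The index genotype then predicts the
   spouse's phenotype (through the index phenotype), but the genotypes
   themselves stay uncorrelated.
3. **Shared environment** — a couple-level factor raises both
   phenotypes.  Neither the cross-partner MR estimate nor the genotype
   correlation moves.

The three diagnostics — adjusted phenotypic correlation, cross-partner
2SLS estimate, cross-spouse GRS correlation — therefore separate the
mechanisms, and the whole package is organised around computing them.

## Generative model of the synthetic cohorts

Per person, the phenotype is

    X = alpha_g * G + sqrt(c_share) * C + e,

with G the standardized unweighted genetic score (sum of independent
Hardy–Weinberg dosages), C a standard-normal couple-shared factor and
e Gaussian noise whose SD defaults to sqrt(1 − alpha_g² − c_share) so
the phenotype has unit variance.  Mechanisms:

* **Interaction**: the reciprocal simultaneous system
  X_f = b_f + t·X_m, X_m = b_m + t·X_f with |t| < 1, solved exactly:
  X_f = (b_f + t·b_m)/(1 − t²).  With independent partners this implies
  corr(X_f, X_m) = 2t/(1 + t²) — the closed form the tests check.
  One-directional influence is available
  (`interaction_direction="male_to_female"` etc.); reciprocal is the
  default because neither direction is privileged a priori.
* **Assortment**: Gaussian-copula rank matching on the pre-partnership
  phenotype.  Each male's matching latent is
  rho_a·U_m + sqrt(1 − rho_a²)·eta (U = normal scores); sorting females
  by phenotype and males by the latent and pairing by rank achieves
  corr(X_f, X_m) ≈ rho_a and an induced GRS correlation
  ≈ rho_a·alpha_g² — the moment oracle used in the tests.  No mate-choice
  mechanism is claimed beyond its copula; matching happens before the
  shared-environment and interaction terms are applied, which is the
  temporally coherent ordering.
* **Confounding**: the shared factor contributes a fraction `c_share`
  of variance to both partners, so corr(X_f, X_m) ≈ c_share while both
  genetic diagnostics stay null.  No published magnitude exists for this
  mechanism; the default `c_share = 0.3` was fixed once as a visibly
  non-null but sub-pathological value.

The `ukb-like` preset (47,050 couples, GRS variance fraction 0.006,
partner effect 0.13 SD/SD, 70 variants) mirrors the scale of the
published sleep-duration analysis, where unweighted scores explain
0.1–1.4% of trait variance.  `expected_grs_variance` converts a
per-allele effect and a MAF vector into the implied variance fraction
(alpha² Σ 2p(1−p) / total variance) for calibrating new scenarios.

Covariates (ages ≈ N(56.8, 7.3) with correlated spouse age, 8 centres,
two genotyping chips, 10 null PCs) are generated for plumbing realism;
they carry no signal, so adjusted and unadjusted analyses estimate the
same quantities on synthetic data.  The trait battery maps each
person's latent phenotype to questionnaire strings and accelerometer
summaries whose marginals match the published sex-specific category
proportions (thresholded latent Gaussians; one threshold for binary
snoring).  Each trait carries its own loading on the scenario
phenotype plus a small (5% of latent variance) trait-specific
couple-shared component, so same-trait spousal correlations dominate
the cross-trait matrix — the weak-cross-trait structure seen in real
couple data — without altering the scenario mechanisms, which operate
on the scenario phenotype alone.

All randomness flows from one master seed; each operation draws from a
substream derived by hashing the operation label, so adding a consumer
never perturbs existing draws and identical parameters reproduce
cohorts bitwise.

### What the generator does not emulate

Linkage disequilibrium between variants (instrument lists are assumed
pre-pruned), genotyping error, age-dependent trait trajectories,
relationship dissolution, and selection into the cohort.  Passing tests
therefore demonstrate the statistical machinery under the stated
structural model, not robustness to these real-data features.

## Couple and trio inference

Spouse pairs: exact equality on all eight household matching fields
(no tolerance — coordinates are already 1-km quantised), then
exclusions with per-person rule tags: >2 people with identical
descriptors, same-sex pairs, identical paternal *and* maternal ages at
death (both non-missing), relatedness > 0.1 from the supplied IBD
table.  An individual matched into more than one candidate couple
discards all its couples (conservative; logged `ambiguous_multiple_
candidates`).  The exclusion log partitions every rejected candidate.

Trios: candidate parents share IBD1 ≥ 0.425 and IBD2 ≤ 0.10 with the
index; retained parent pairs share mutual IBD1 ≤ 0.20; several
surviving pairs for one index mark the child ambiguous and accept none.
Mendelian concordance is checked on 100 random variants with MAF > 0.3
and call rate ≥ 99.9% (error if fewer exist), accepting at ≥ 95
concordant; a variant is concordant iff the child dosage is producible
from one transmitted allele per parent.

## Encoding conventions

Chronotype is a 1–5 ordinal with "Do not know" as the intermediate
category 3 (excluded from the evening/morning binary); other "Do not
know"/"Prefer not to say" responses are missing.  Ordinals are analysed
as equally spaced integers; binary snoring stays on the 0/1 scale so
regression output is a risk difference.  Standardisation uses the
sample SD (n−1); the IQR outlier rule for accelerometer error counts
uses linear-interpolation quartiles computed *after* flag-based
exclusions.  L5 timing lives on the linear 12–36 h axis (hours from the
previous midnight) and is wrapped only for display.

## Estimators

* **Adjusted Pearson**: residualise both traits on the covariates
  (intercept included, categoricals one-hot dropping one level), then
  Pearson on residuals; Fisher-z CI with variance 1/(n − 3 − k).
  Subtracting the covariate count k from the df is a conservative
  choice; at the cohort sizes of interest it is numerically irrelevant.
* **2SLS**: standard IV estimator with the GRS (or dosage set) as
  instruments; the variance uses the *structural* residuals
  y − X·beta_hat (observed exposure), not the naive stage-2 OLS
  residuals, with denominator n − k.  Dyadic pooling includes each
  person as index and as spouse; couple-clustered sandwich SEs
  (`cov_type="cluster"`) are recommended there because the two
  orientations of one couple are not independent.
* **Sargan**: n·R² of the structural residuals on instruments plus
  covariates, chi-square with J − 1 df; just-identified models return a
  flagged not-applicable result rather than raising.
* **IVW**: fixed-effect weighted mean of per-variant Wald ratios,
  weights ratio_se⁻² with the first-order SE se_gy/|beta_gx|.
* **MR-Egger**: weighted regression of beta_gy on beta_gx (gx oriented
  non-negative, gy flipped with it), weights se_gy⁻²; the residual
  scale is truncated below at 1 (multiplicative random-effect
  convention).  The I²_GX statistic — the heterogeneity decomposition
  applied to the gx estimates — flags regression-dilution weakness.
* **Weighted LAD**: minimises Σ (1/se_gy)|beta_gy − b·beta_gx| through
  the origin, solved exactly as the weighted median of the ratios with
  weights |beta_gx|/se_gy.  The default SE bootstraps ratio rows;
  `bootstrap_couples_lad` resamples couples and recomputes the ratios
  when individual-level data are at hand, which respects the dyadic
  dependence at higher cost.
* **Meta-analysis**: fixed-effect (Q, I² = max(0,(Q−df)/Q), P_het) and
  DerSimonian–Laird random effects.  `ci_to_se` recovers SEs from
  printed symmetric intervals; one published subgroup interval
  (0.17; 0.05, 0.39) is asymmetric about its estimate — the width is
  used regardless, and this reproduces the printed I² and P_het.
  Tertiles use linear-interpolation quantiles with ties to the lower
  stratum.

## Worked-example inputs

`dyadmr.reference` ships the printed summary tables of the UK Biobank
spousal sleep analysis (marginals, MV/2SLS estimates, subgroup CIs,
instrument counts).  They are inputs, not outputs: the package
recomputes the z-tests, heterogeneity statistics, clock rendering and
prevalence from them at run time.  The ease-of-waking z-test row does
not reproduce from its rounded inputs (recomputed ≈ 0.50 vs printed
0.503) and is excluded from the exact checks.

## Problem sizes

Simulation-based checks use 20,000 couples for single-shot scenario
signatures, 500 × 2,000 couples for type-I calibration under
confounding, 500 × 2,000 for interaction CI coverage, and 200
replicates of the full 47,050-couple preset for recovery of the 0.13
partner effect — sizes at which Monte-Carlo bands are tight enough to
be informative while the whole suite stays cheap on one core.
`scripts/acceptance.py` reuses the same machinery with 50 recovery and
200 calibration replicates.

## Known limitations

Mixed scenarios interact: rank matching precedes the interaction
solve, so the achieved assortment correlation under `mixed` is only
approximately rho_a.  The per-variant Wald machinery assumes
independent instruments; correlated variants would need a generalised
weighting it does not implement.  MR-Egger inherits its usual weak
instrument sensitivity (visible in the I²_GX diagnostic on the default
synthetic instruments).  The 23andMe-style dialect implements encoding
and age-residualised correlation only, matching the replication role
that dialect plays in the analysis design.
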