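# Methods

This note documents the models, conventions and numerical choices behind
`equifert`, in the order the pipeline uses them.

## Trait derivation

All ages are in months. For a mare with foaling ages `t1 < … < tF` and an
optional culling age `c`:

- AFF = t1, ALF = tF, FN = F
- IF12 = t2 − t1 and AIF = (tF − t1)/(F − 1), both defined only for F ≥ 2
- PL = (c if known else tF) − t1; a still-active mare's window ends at her
  last foaling
- RE = 100 · F / optimal, where `optimal = floor(PL/12) + 1`

The optimal-foaling count assumes one foaling per year starting at the
first foaling: the foaling that opens the window plus one per completed
12-month year. Under this convention an exact yearly schedule scores
RE = 100%, a single foaling scores 100%, and foaling every ~11 months can
reach 150–200%. The alternative ceiling convention
(`max(ceil(PL/12), 1)`) is available via `optimal_rule="ceil"`; the floor
convention is the default because it keeps RE bounded by a realistic
maximum and treats the opening foaling as already "earned". Undefined
traits are stored as missing (NaN), never zero-filled, and descriptive
statistics (`describe`) exclude missing values per trait, using the n−1
denominator for SD and CV% = 100·SD/mean.

## Relationship matrices

**A** is built by the tabular method, **F** by the Meuwissen–Luo
ancestor-tracing algorithm (the two agree exactly: `diag(A) = 1 + F` is a
tested invariant), and **A⁻¹** by Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances. All three accept any
ordered pedigree (parents before offspring); unordered input raises an
error telling the caller to recode.

Genotype QC removes, in this fixed order: individuals with call rate
< 0.95, SNPs with call rate < 0.95, then monomorphic SNPs and SNPs with
MAF < 0.05. Remaining missing dosages are imputed to `2p` (mean
imputation). The order matters only at the margins but is fixed for
reproducibility, and the filter is idempotent.

**G** follows VanRaden: `G_raw = ZZ′ / (2Σ pᵢ(1−pᵢ))` with `Z` the dosage
matrix centered by `2pᵢ`, then `G = 0.95·G_raw + 0.05·A22`. Allele
frequencies default to the observed genotyped sample — base-population
frequencies are rarely available in practice — with a `freq` argument for
callers who have them. No Vitezica-style rescaling of G toward A22 is
applied by default; the blend alone guarantees positive definiteness
whenever A22 is positive definite (smallest eigenvalue ≥ 0.05 × that of
A22, a tested property).

**H⁻¹** adds `G⁻¹ − A22⁻¹` on the genotyped block of A⁻¹. Two degeneracies
pin the implementation down: an empty genotyped set returns A⁻¹ unchanged,
and a fully genotyped population cancels the pedigree terms, leaving G⁻¹.
The dense closed-form H is also provided; tests verify H⁻¹ against its
direct inversion at 1e-8.

## Mixed model and REML

The multi-trait model is `y = Xb + Za + e` with `var(a) = K ⊗ G0` and a
per-animal residual covariance taken from the observed-trait submatrix of
R0 (the canonical unequal-design treatment; each mare has at most one
record per trait). Fixed effects are trait-specific: intercept, inbreeding
covariate, age at last foaling (standardized; omitted for AFF, ALF and
IF12, which are themselves age measurements), and three class effects with
the first level of each class constrained to zero.

Variance components are estimated by EM-REML with AI (average-information)
acceleration on Henderson's equations:

- Animals without records are absorbed before iterating. The restricted
  likelihood depends on K only through its submatrix at recorded animals,
  so iterating on the reduced system is exact, and the full system is
  solved once at convergence for all EBVs and PEVs. Passing the dense K
  alongside K⁻¹ skips one matrix inversion.
- Every iteration factorizes the (reduced) coefficient matrix once; the EM
  update, the analytic gradient and the AI matrix all reuse that
  factorization. The first step is always EM; afterwards AI/Newton steps
  are taken with step-halving back toward the EM update whenever a step
  would leave the positive-definite cone, and the engine falls back to EM
  when the likelihood decreases. Pure EM (`method="em"`) is available and
  reaches the same optimum (a tested cross-check, including under missing
  data, where the EM update's fixed point coincides with the vanishing
  analytic score).
- Convergence: relative change of every estimable (co)variance < 1e-8
  (configurable), capped at 500 iterations with a warning and a flagged
  result. A variance collapsing below 1e-6 of the phenotypic variance is
  treated as a boundary estimate (flagged) and counts as converged once it
  is decreasing; diagonals are floored at 1e-8 of the phenotypic variance.
- Starting values: half the phenotypic variance to each component.
- Standard errors come from the inverse AI matrix at convergence; h² SEs
  use the delta method. Residual covariances between traits never observed
  together are pinned at zero, and `constrain_diagonal=True` fits the
  independent-traits model.
- Reported log-likelihoods omit an additive constant independent of the
  components, which cancels in all comparisons the package makes.

Reliability defaults to the inbreeding-adjusted form
`r² = 1 − PEV/((1+F)σ²ₐ)`, appropriate in an inbred closed studbook where
`var(aᵢ) = (1+Fᵢ)σ²ₐ`; the unadjusted form is behind a flag. Comparisons
always use the same formula on both sides, so stratified gains are
insensitive to this choice. Values are clipped to [0,1] with clip counts
recorded on the fit.

## Synthetic populations

The generator emulates a closed studbook: discrete generations under
random mating (no selfing; parent–offspring matings impossible by
construction, full-sib matings avoided unless explicitly enabled), sires
drawn with replacement so progeny counts vary, balanced sexes, and a
configurable genotyped fraction sampled uniformly. SNPs are unlinked and
biallelic, founders drawn at frequencies uniform on `maf_range`,
descendants gene-dropped one gamete per parent. Breeding values follow the
pedigree recursion exactly — founders N(0, G0), non-founders parent
average plus Mendelian sampling with variance `(0.5 − 0.25(F_s+F_d))·G0` —
so the simulated `diag(A) − 1` equals the realized inbreeding by
construction. Phenotypes are recorded for females only (flag to record
both sexes), with true fixed effects expressed in phenotypic-SD units:
inbreeding depression slope −0.8 SD per unit F, age slope 0.2 SD, and
class effects of 0.1–0.25 SD. Foaling careers use a first-foaling age of
N(64, 15) months, a per-year foaling probability of 0.6 with ±3 months of
jitter (minimum gap 10 months), and a productive window of N(130, 60)
months; 30% of mares are left still-active. These defaults land the
derived trait means near a realistic studbook's scale (AFF ≈ 64 months,
AIF ≈ 20 months, PL ≈ 126 months).

Default trait variances are representative REML estimates for mare
fertility in a closed studbook (h² from 0.070 for IF12 to 0.349 for ALF).
Genetic correlations between the traits default to zero because no
reliable reference values exist for them as a set; the multi-trait
machinery accepts any positive semi-definite correlation matrix and is
tested with nonzero correlations. Class-assignment frequencies are
configurable and make no claim to match any particular association's
distribution.

What the generator does *not* emulate — linkage and LD between SNPs,
selection, mutation, genotyping of influential animals rather than a
uniform sample, and overlapping generations — bounds what passing tests
show: the pipeline's algebra and estimators are correct under the model's
own assumptions, not that real data meet those assumptions.

## Comparison semantics

Gains are always `100·(mean_ss − mean_ped)/mean_ped` from unrounded
stratum means, reported as-is (negative gains are not clipped). Progeny
counts come from the pedigree and the progeny-count strata cover sires
only; the initial-reliability split uses the pedigree fit's r² at a
configurable threshold (default 0.6, or `"median"` for a per-trait median
split, which suits simulated populations whose reliabilities rarely reach
0.6). The headline comparison evaluates both relationship matrices at the
same (true, simulated) variance components, isolating the matrix effect on
PEV from variance-estimation noise — the regime of interest, since
estimated components barely differ between the two methods; re-estimation
per method is a flag (`estimate=True`) away.

## Problem sizes

The test suite runs populations of 160–900 animals for unit and property
tests, ten replicates of ≈ 4000 animals (≈ 2000 recorded mares, 30%
genotyped, 3000 SNPs) for the h²-recovery harness, and ten replicates of
750 animals for the reliability-gain structure; the acceptance script uses
1800 animals, 20% genotyped and 2000 SNPs. At these sizes every factorization
is dense and exact; the conjugate-gradient solver and the sparse A⁻¹/H⁻¹
storage are the path to larger evaluations, but no large-scale
approximations (APY, metafounders, unknown-parent groups) are implemented.

## Known limitations

- Single record per mare per trait: permanent-environment and maternal
  effects are unidentifiable and not modeled.
- No forward-validation (LR) reliabilities; reliabilities are model-derived
  PEV reliabilities only.
- The EM/AI engine targets desk-scale problems (≤ ~5000 animals per fit);
  national-evaluation scale would need sparse selected inversion.
- Sex chromosomes, twin foalings and date-to-age conversion are out of
  scope; foaling ages are inputs.
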