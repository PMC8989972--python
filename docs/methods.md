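# Methods

`founderlip` implements the quantitative-genetics toolchain used to
dissect a lipidome (hundreds of molecular lipid species plus the four
traditional lipids) measured in a founder population: a closed,
multi-generation pedigree descended from a small founder set, in which
rare alleles can drift to unusually high frequency and long shared
haplotypes create strong local linkage disequilibrium (LD).

## Phenotype preparation

Each trait is regressed on age, age², sex and technical batch factors
by ordinary least squares (traditional lipids skip the technical
factors so that lipid and lipidome analyses stay comparable), and the
residuals are mapped to normal quantiles by the rank-based inverse
normal transform

    z_i = Φ⁻¹((r_i − c) / (n + 1 − 2c)),   c = 3/8 (Blom, configurable)

with average ranks for ties, so equal inputs receive equal outputs and
the transform is deterministic. Prepared traits are unit-SD normal
scores; downstream effect sizes are therefore in SD units. No
medication adjustment is applied. Categorical covariates expand to
indicator columns against a reference level; an exactly collinear
design is an error naming the aliased terms rather than a silent drop.

## Relatedness structures

* **Kinship** φ(i,j) — probability that one random allele from each of
  two individuals is identical by descent (IBD) — is computed by the
  standard tabular recursion in topological (parents-first) order:
  founders have φ(i,i)=½ and are mutually unrelated; otherwise
  φ(i,i)=½(1+φ(f,m)) and φ(i,j)=½(φ(f,j)+φ(m,j)). The additive
  covariance structure is A = 2φ, so the additive variance component is
  on the trait-variance scale and h² = σ²_a/σ²_p.
* **Dominance (fraternity)** d(i,j) — probability of sharing the whole
  genotype IBD — uses the product-of-parental-kinships formula
  d(i,j) = φ(f_i,f_j)φ(m_i,m_j) + φ(f_i,m_j)φ(m_i,f_j), d(i,i)=1,
  zero against founders. The formula is exact for non-inbred pairs; it
  is applied to all pairs and a warning lists inbred individuals, whose
  pairwise entries are approximate. Full condensed-identity
  (nine-coefficient) computation is out of scope; the approximation
  matches common fraternity-matrix practice.
* **SNP GRM** — per-variant standardized dosages
  w = (g − 2p)/√(2p(1−p)) averaged over variants, G = WW′/m, with
  sample allele frequencies and mean imputation of missing dosages
  (keeps G positive semidefinite). Monomorphic variants are an error.
* **Class covariance** S = XX′/m from the mean-centered, unit-variance
  (denominator n) species of one lipid class, so trace(S) = n and the
  fitted proportion for a class component is on the same
  heritability-like scale regardless of how many species the class
  contains. The per-m scaling is a documented choice; only the
  centering/normalization is forced by the construction.

Genotype QC before any GRM or association work: call rate (default
missingness ≤ 2%), folded MAF ≥ 0.01, and a plain 1-df chi-square
Hardy-Weinberg test at p ≥ 1e-10 (hard calls only; dosage variants are
not HWE-testable and are filtered on the other two criteria). The
thresholds sit in one `QcThresholds` object and are pipeline options.

## Variance decomposition

The phenotypic variance is partitioned as
σ²_p = σ²_1 + … + σ²_n + σ²_e, each component tied to a random effect
b_k ~ N(0, σ²_k Σ_k) with Σ_k any of the structures above. Estimation
is by restricted maximum likelihood (REML; plain ML is available and is
required when comparing models with different fixed effects) using
average-information (AI) updates. Numerical policy:

* start values split var(y) equally across components + residual;
* an AI step that would push a component negative triggers a nested
  re-maximization with that component fixed at a small floor, compared
  against an EM-style fixed-point step (θ·y′PK Py / tr(PK)); the
  better candidate is taken and step-halving guards monotonicity;
* components driven to the floor with negative score are pinned to
  exactly 0, flagged `boundary`, and the remaining components refit, so
  the result is the constrained maximum over σ² ≥ 0;
* convergence: relative log-likelihood change < 1e-8 and projected
  gradient norm < 1e-6, max 200 iterations; non-convergence raises an
  error carrying the iteration trajectory;
* a component matrix numerically proportional to the identity is
  rejected as non-identifiable (it cannot be separated from the
  residual);
* with a single relatedness component the model is rotated into the
  component's eigenbasis, making every iteration O(n); the dense path
  covers multi-component models. Both paths maximize the same
  criterion (verified against a grid oracle and the balanced full-sib
  ANOVA closed form in the tests).

Standard errors come from the inverse AI matrix at the solution.
Proportions λ_k = σ²_k/σ²_p are reported alongside the raw variances;
the additive component's λ is h².

**Model comparison.** Nested models are compared by likelihood ratio
test. Because the tested variance sits on the boundary under the null,
the default null distribution is the ½:½ mixture of a point mass at 0
and χ²₁ (plain χ²₁ selectable). REML likelihoods are only compared
across identical fixed effects; otherwise ML is required. The empirical
size of the mixture test is verified by simulation in the tests.

**Sequential selection.** Greedy forward selection over candidate
components (e.g. the 13 lipid-class covariance matrices for a
traditional-lipid trait): at each step every remaining candidate is
added to the current model, the smallest LRT p wins, and selection
stops when no candidate reaches α = 0.05. Ties break by candidate list
order; failed fits are skipped with the reason recorded; the full
audit trail is returned. The pipeline replicates the screening rule of
restricting class decompositions to traits whose baseline
(kinship + enriched-variant-adjusted) heritability has p < 0.01.

## Bivariate genetic correlation

For a trait pair the stacked model has genetic covariance G ⊗ A and
residual E ⊗ I with unconstrained 2×2 G and E (no Cholesky
reparameterization). After rotating into the eigenbasis of A the
covariance is block diagonal in 2×2 blocks, so ML evaluation is O(n);
optimization is L-BFGS-B from three starts with a Nelder-Mead polish
(the profile is flat near the optimum). Because G is unconstrained,
ρ_g = σ_g12/√(σ_g1 σ_g2) can leave [−1, 1] — this happens regularly
when one or both traits have low heritability — and such estimates are
flagged and reported missing in matrix outputs rather than clipped.
A numerically zero heritability masks ρ_g as undefined, and
out-of-range residual correlations are masked symmetrically (an
extension of the genetic-side rule, for consistency). Phenotypic
correlations are pairwise-complete Pearson.

## Association scans

GWAS uses the standard two-stage LMM: the null model
(trait ~ intercept + optional conditioning genotypes, additive
component by REML) fixes V̂; each variant's effect is then the
generalized-least-squares estimate under V̂ with a Wald t test on
n − p − 1 residual degrees of freedom, with the residual scale
re-estimated per variant. With an identity-proportional relatedness
structure this reduces exactly to per-variant OLS, which the tests use
as a closed-form oracle. The VCF alt allele is the effect allele;
effects are in SD units of the prepared trait. Monomorphic variants
and variants collinear with the conditioning set are skipped with the
reason recorded.

* **Conditional analysis.** Within a locus (±1 Mb around the index
  variant in the pipeline), the top variant is added to the
  conditioning set and the region rescanned until nothing is below the
  threshold; the ordered conditioning set is the list of independent
  signals. In a founder population, a drifted causal variant sits on a
  long haplotype and drags dozens of proxies to genome-wide
  significance; conditioning on the causal variant collapses them, the
  basis of the replication-exclusion argument.
* **Multiple testing.** The trait correlation matrix (prepared traits,
  complete cases) is eigen-decomposed; the significance threshold is
  the base genome-wide level (5e-8) divided by the smallest number of
  principal components whose cumulative eigenvalue fraction reaches
  0.95. For 355 lipid species with 110 such components this gives
  4.5e-10; everything between the base level and the adjusted
  threshold is the suggestive band. Fixed-list replication look-ups
  use plain Bonferroni (α/m).
* **Replication-exclusion power.** For a standardized effect β at
  minor allele frequency q in a replication sample of n, the two-sided
  Wald noncentrality is β·f·√(2q(1−q)n) with f ∈ {1, 0.5} (0.5 halves
  the discovery effect against winner's curse), and power is the
  shifted-normal mass beyond ±z_{1−α/2}. High computed power combined
  with a null replication result supports excluding a variant as
  causal. The analytic form is validated against Monte-Carlo OLS
  rejection rates in the tests.

## Synthetic data

The generator produces the study's data shapes with known truth:

* **Pedigree** — non-overlapping generations from a closed founder
  set; couples pair within a generation (random, or biased toward
  related mates to generate inbreeding and exercise the dominance
  warning path); Poisson offspring counts. Defaults (170 founders, 6
  generations, mean sibship 2.6, analyzing the last two generations,
  ≈ 600–650 subjects) reproduce the scale of a founder-population
  lipidomics cohort while keeping a desk-scale run; a 14-generation
  history is scaled down to 6 because the kinship spectrum relevant to
  estimation (sibs through second cousins) saturates quickly.
* **Gene dropping** — founder haplotype alleles drawn at configured
  frequencies or seeded as exact copy counts (one to a few copies in
  founders drift across replicates, occasionally reaching ≥ 10× the
  founder frequency — the enriched-variant scenario); fair meioses,
  independent across variants except within LD blocks, which share one
  meiosis per transmission (no intra-block recombination) and whose
  proxy alleles copy the causal founder haplotype allele with
  probability r (default 0.95). This produces the long-haplotype LD
  needed for the conditional-analysis demonstration without a full
  recombination map, which is deliberately out of scope.
* **Traits** — each trait is a sum of component draws (additive =
  Cholesky factor of A times a standard normal vector, dominance,
  class structures from already-simulated species), each draw rescaled
  so its sample variance equals the configured fraction exactly;
  variant effects are added in SD units and covariates (age, sex,
  batch) are mixed in with known coefficients (and optionally
  exponentiated) to exercise phenotype preparation. Within-class
  correlation comes from a shared latent factor (default 0.4). Because
  only the chance cross-covariance between component draws perturbs
  the total, single-replicate totals fluctuate a few percent around
  the configured variance while the replicate mean matches it.
* **Randomness** — counter-based (Philox) streams keyed by
  (seed, operation, item): the same seed gives byte-identical outputs
  and adding variants does not perturb trait draws.
* The same machinery provides the independent Monte-Carlo oracle for
  kinship and dominance: dropping uniquely labeled founder alleles and
  measuring allele/genotype sharing frequencies.

What the generator does not emulate: measurement-technology artifacts
beyond generic batch shifts, lipid-species missingness mechanisms,
genotyping/imputation error, assortative mating, and realistic
recombination/LD beyond single-block co-segregation. Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the stated model, not robustness to those real-data features.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at the cohort's scale where the check is
about recovery (n = 600 subjects; 200 replicates for h², 100 for the
class decomposition and the genetic correlation) and at reduced scale
where the check is about calibration of a test statistic (n = 200,
1000 null replicates for the LRT size; 5000 variants for the null
GWAS; 50 replicates of a 51-variant locus for conditional exclusion;
10⁵ gene drops for the kinship/dominance oracle). The acceptance
script uses 60 replicates for the class decomposition and 80 for the
genetic correlation — enough for the replicate means to sit well
inside the tolerances asserted in the test suite.

## Known limitations

* Dominance under inbreeding is approximate (see above); whether a
  given reference implementation corrects for inbreeding exactly is
  not asserted.
* The bivariate model covers pairs only; no >2-trait models.
* ρ_g estimates on flat likelihood ridges (masked, out-of-range cases)
  are reported as missing because their exact values are not
  numerically stable — by design, since they were never interpretable.
* The two-stage GWAS fixes V̂ from the null model; exact per-variant
  REML refitting is not performed (standard practice at GWAS scale,
  and the per-variant residual-scale re-estimation recovers exact OLS
  behavior in the unrelated limit).
* The pipeline's resume logic keys on the config digest and output
  existence; it does not hash upstream input files.
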