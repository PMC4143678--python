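# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `egvkit`, in the spirit of a software methods
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Relatedness

**Expected (pedigree) relatedness.**  `R = 2 Phi` is computed by the
recursive (tabular) kinship algorithm in topological order: founders
are mutually unrelated with self-kinship 1/2; for non-founder *i* with
parents *f*, *m*, `phi(i,j) = (phi(f,j) + phi(m,j)) / 2` for previously
processed *j* and `phi(i,i) = (1 + phi(f,m)) / 2`.  The method is exact
(including inbreeding: the diagonal of R is `1 + F`), O(n²) memory, and
is validated in the tests against a vectorised Monte-Carlo gene-drop
oracle (200,000 single-locus drops).

**Marker-based relatedness.**  The KING-robust estimator
`phi_hat = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))` over
pairwise-complete SNPs, computed for all pairs at once via indicator
matrix products.  It is robust to allele-frequency misspecification, the
reason family studies prefer it.  SNPs with >10% missingness are dropped
globally; "common" means folded MAF >= 0.05 (configurable), "all" keeps
every polymorphic site.  The diagonal of an empirical matrix is fixed at
1: no marker-based inbreeding estimate is attempted, because the
downstream model only requires a valid correlation structure.  Pairs
with a zero denominator (no heterozygous sites) raise an error naming
the pair rather than silently producing NaN.

**Positive-semidefinite repair.**  Empirical matrices are generally
indefinite and must be repaired before they can serve as a covariance.
`nearest_correlation` implements Higham's alternating projections with
Dykstra's correction between the PSD cone and the unit-diagonal set.
It stops when the successive-iterate max-norm change falls below `tol`
(default 1e-8) *and* the returned iterate's smallest eigenvalue is
>= -tol; non-convergence within `max_iter` (default 500) raises an
error carrying the last residual.  The implementation is hand-written
because these convergence semantics are part of its contract; the test
suite cross-checks it against `statsmodels.stats.correlation_tools.corr_nearest`
and against an independently coded constrained minimizer of the
Frobenius distance on small cases.

**Unrelated subset.**  PCA is anchored on a maximal set of mutually
unrelated individuals (all pairwise `R < 0.05` by default).  The greedy
selection visits candidates in ascending order of how many others they
are related to (ties by id): members of large sibships are excluded
before their founder parents, which is both the behaviour one wants
(founders carry the independent genomes) and deterministic.

## Covariates

Markers are LD-pruned by a greedy sliding window (defaults: window 50
SNPs, step 5, r² <= 0.2; within a window the worst pair is resolved by
dropping its lower-MAF member).  PCA standardises dosages by
`sqrt(2p(1-p))` with `p` estimated in the unrelated subset (centre-only
available), takes loadings from an SVD of the unrelated rows, and
scores every genotyped sample with those loadings.  PC scores are then
propagated to the pedigree by the parental-mean rule: founders keep
their own scores, every non-founder receives the average of its two
parents' scores, recursively in generation order.  This is the only
projection implemented; it requires every founder to be genotyped,
which the simulator guarantees.

## Polygenic model and EGV

`fit_polygenic` maximises the multivariate-normal likelihood of
`y ~ N(Xb, sigma_p^2 [h^2 R + (1-h^2) I])` using one eigendecomposition
of `R` (a 1e-8 ridge is added first for numerical safety): in the
rotated basis the covariance is diagonal, `b` and `sigma_p^2` profile
out analytically, and `h^2` is optimised on [0,1] by bounded scalar
minimisation (tolerance 1e-8), with explicit endpoint checks so
boundary estimates are returned as exact 0/1 with a flag.  ML is the
default (matching the behaviour of the variance-component software
this workflow descends from); REML is available and is used where
designs have many fixed-effect columns.  If `R` is numerically
proportional to the identity the likelihood is flat in `h^2`; the fit
returns the `h^2 = 0` boundary with a warning rather than an arbitrary
interior point.

The EGV is computed as `R (R + lambda I)^-1 (y - Xb)` via the same
eigendecomposition — algebraically identical to the textbook
`(I + R^-1 lambda)^-1 (y - Xb)` but without forming `R^-1`.  Its
error-variance matrix `E` is defined as the BLUP prediction-error
variance `Var(EGV - g) = sigma_g^2 R - sigma_g^2 R (R + lambda I)^-1 R`
(the natural choice where only "an error variance matrix" is specified);
in the eigenbasis its eigenvalues are `sigma_g^2 d lambda / (d + lambda)`.
Each phenotype replicate is fit separately — covariate values are fixed
across replicates but their effects, and the variance components behind
`lambda`, are re-estimated per replicate.  Replicates whose
`sigma_g^2` estimate hits zero are skipped (the EGV is undefined
without additive variance) and reported.

On fully model-consistent synthetic data the refit heritability of the
EGV typically reaches the upper boundary: the EGV is a deterministic
smooth of the residual with almost no individual-specific noise floor,
so the amplification check in the tests (EGV heritability at least 1.5
times the raw trait's) is a lower bound, not a point prediction.

## Association (MGA)

Each SNP is tested by a likelihood-ratio with one added fixed effect,
under the family covariance written as variance proportions

    Omega = sigma_p^2 (2 Phi h^2 + I e^2 + En eps),  h^2 + e^2 + eps = 1.

The expected (pedigree) kinship enters `Omega` for every trait,
including the empirically derived EGVs.  `En` is the EGV error-variance
matrix normalised to unit mean diagonal, making `eps` a unitless
proportion; with `eps = 0` the model reduces exactly to the standard
polygenic MGA (unit-tested).  `include_E` defaults to on for EGV traits
and off for the raw phenotype.  All variance proportions are
re-optimised in both the null and the alternative model; the null is
fit once per (trait, replicate) and reused across SNPs.

Numerics: everything is rotated into the eigenbasis of `2 Phi`.  When
`En` derives from the same matrix it is diagonal in that basis and each
profile-likelihood evaluation costs O(n p²); otherwise a dense
Cholesky path is used.  The two-proportion optimisation runs L-BFGS-B
on a box reparameterisation of the simplex, warm-started from the null
model's estimates plus two fixed starts.  LRT values are clamped at
zero and referred to chi-square(1).  Missing dosages are mean-imputed
per SNP; monomorphic SNPs produce skip records and per-SNP numerical
failures produce flagged records — a scan never aborts.

## Evaluation

A significant SNP is a true positive iff its squared correlation with
any causal SNP of a gene on the same chromosome reaches the block
threshold (default 0.2).  No haplotype block segmentation is attempted:
max-r² to the causal set is the simplest faithful operationalisation
and is fully testable.  A hit is attributed to the best-matching gene
(ties broken by genomic distance, then name) and additionally counts
for every gene clearing the threshold, which is what produces the
characteristic pattern of one strong gene dragging its neighbours into
the per-gene table.  Monomorphic (unclassifiable) hits count as false
positives.  FDR is pooled across replicates (false positives over total
significant); a per-replicate mean is available.  Two thresholds are
kept distinct and configurable: scan significance 5e-8 and evaluation
inclusion 5e-7.

`gene_variance_fraction` estimates the share of phenotypic variance a
causal gene explains: a joint GLS regression of the phenotype on the
gene's dosage columns under the fitted polygenic covariance (REML), with
the quadratic-form bias `tr(Cov(b) S)` subtracted from `b'Sb`.  Plain
OLS R² is structurally inflated in family data — beyond the usual k/n
term, rare causal variants act as family indicators and absorb part of
the family-structured polygenic variance — so the mixed-model estimator
is the appropriate one in pedigrees.  When measuring one gene the other
causal genes' dosages (reduced to a linearly independent set by pivoted
QR) are included as fixed covariates, removing their fixed chance
correlation with the measured gene.

## Synthetic data

The generator emulates a family blood-pressure study:

- **Pedigrees.**  20 extended families, 3 generations by default: a
  founder couple, sibships of size `1 + Poisson(sibship_mean - 1)`
  (default mean 5.4), spouses married in as new founders at every
  non-terminal generation.  Family sizes are redrawn until the total is
  within 10% of the 847-person target.
- **Founder haplotypes.**  Designed allele frequencies (a rare fraction
  at MAF 0.001-0.01, the rest uniform on 0.05-0.5) with LD generated by
  a Gaussian-copula AR(1): a latent autoregressive series (coefficient
  `rho`, default 0.9) thresholded at each site's frequency quantile.
  This preserves the designed marginal frequencies exactly — a rare
  site stays rare regardless of its neighbours — while giving monotone
  LD decay in `rho`.
- **Gene drop.**  Each meiosis transmits a recombined parental
  haplotype (crossovers Poisson per chromosome, uniform positions),
  yielding dosages whose realized IBD sharing matches the pedigree
  expectation.
- **Causal architecture.**  Five genes on round-robin chromosomes: 15
  SNPs at 7.79% of trait variance, 14 at 4.67%, 16 at 3.87%, 8 at
  2.06%, and a 2-SNP gene at 0.3% — 55 causal variants, of which 10 are
  designed rare (<1%) and 28 below 5%.  Causal sites are guaranteed at
  least two alternate copies among founder haplotypes so no causal
  column is monomorphic.  Within a gene, one lead SNP carries 60% of
  the gene's variance (configurable); effect sizes are calibrated
  against the *realized* dosage covariance so each gene's causal score
  has exactly its designed variance despite within-gene LD.
- **Phenotypes.**  `y = mean + b_age (age - mean_age) + b_sex sex +
  causal score + g_poly + e` on an SBP-like scale (mean 120, total
  variance 200 mm Hg²); age and sex effects are calibrated to 7% and 3%
  of total variance, the polygenic deviate is multivariate normal
  around `2 Phi` (Cholesky), and the environmental share is the budget
  remainder.  Genotypes, covariates and causal scores are fixed across
  the (default 100) replicates; `g_poly` and `e` are redrawn.  True
  per-individual genetic values are returned for evaluation.
- **Randomness.**  Everything flows from one master seed through named
  substreams (pedigree, haplotypes, drop, covariates, phenotypes), so
  any stage is independently re-runnable and byte-reproducible.

**What the simulator does not model:** coalescent-accurate haplotype
diversity, demographic history, genotyping error, household/shared
environment, dominance, X-linkage, or ascertainment.  Passing tests on
these data show the estimators are correct under the stated model; they
do not certify behaviour under real-data violations of it (population
stratification beyond two PCs' worth, non-normal residuals, shared
households mimicking kinship).

## Problem sizes and defaults

Desk-scale defaults keep every stage interactive: 4 chromosomes of 500
SNPs for the main study (the dense-marker kinship checks use ~22,000
sites with milder LD), 50 phenotype replicates in the validation runs,
2,000 null tests for association calibration (four polygenic traits by
500 gene-dropped null SNPs), and 200,000 drops for the Monte-Carlo
kinship oracle.  All are configuration, not constants.

## Known limitations

- Between-family KING estimates use the same within-family robust
  denominator (homogeneous-population assumption); no ancestry-aware
  correction is implemented.
- The parental-mean PC projection requires genotyped founders; there is
  no loadings-based projection for ungenotyped ancestors.
- The per-gene hit attribution lets one SNP count for several
  overlapping genes by design; per-gene counts are therefore not
  disjoint.
- REML standard errors for `h^2` are not reported; only point estimates
  and log-likelihoods.
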