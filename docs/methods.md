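# Methods

This note records the statistical models, the defaults, and the numerical
and design choices behind `gxemap`, in the order the modules run.

## Synthetic populations and trials

The generator emulates a multi-family maize experiment: six biparental
doubled-haploid (DH) families of sizes 17, 22, 35, 38, 44 and 78 (one of
them a BC1DH), evaluated in seven macro-environments named
`year.location.Plevel` under an augmented alpha design with two replicates,
blocks nested in replicates, and the checks Zheng58 and Chang7-2 in every
block.

**Meiosis.** Crossovers follow the Haldane model: a Poisson process with
intensity one per Morgan along the genetic map and no interference, with a
fair starting homolog. This is the simplest process consistent with a cM
map. An F1DH line is a doubled F1 gamete (1:1 segregation); a BC1DH line is
a doubled gamete of an F1 × recurrent-parent individual, realized as two
successive mosaic draws (3:1 toward the recurrent parent, which is always
parent 1 of the family spec). The generator does not hard-code which
family is the backcross; the six-family default marks SXDF.

**Founders.** Within a family the two parents are fully homozygous; a
marker is polymorphic within a family with probability
`polymorphic_frac` (default 0.7 in `simulate_families`), otherwise both
parents share an allele. The shared-allele loci create both the
within-family monomorphic markers that the bin-projection step must handle
and the between-family relatedness that makes families cluster.

**Phenotypes.** Plot value = `mu + g_i + ge_ij + Σ_q x_iq·beta_q(env)
+ (1 + b_i)·h_j + rep + block + e`, with `e ~ N(0, sigma_j^2)`
heteroscedastic per environment. The polygenic value `g` is built by
default from 200 random marker effects rescaled to the target variance, so
family structure propagates into the phenotype; `ge_ij` is an optional iid
line-by-environment effect used to plant an exchangeable interaction
variance; planted QTL carry arbitrary per-environment effect vectors
(additive / divergence / convergence / crossover patterns). Every
generated effect is stored in a truth ledger (JSON-serializable), so
recovery tests never re-derive truth from data. Checks get fixed
genotypic values and are flagged; they are excluded from the line set used
for GWAS and prediction.

**What the generator does not emulate:** sequencing reads, recombination
hotspots, interference, dominance and epistasis, spatial field trends, and
environmental covariates. Passing tests therefore demonstrate that the
estimators recover the assumed generating structure at trial scale, not
that real field data satisfy those assumptions.

**Desk scale.** Default examples use ~300–1000 markers instead of a
full resequencing panel; the marker count is a parameter everywhere.

## Genotype pipeline

Marker filters keep MAF ≥ 0.05, missing rate ≤ 0.3, heterozygosity ≤ 0.3
(boundaries inclusive), with an optional mapping-quality pre-filter
(INFO/MQ ≥ 5) and an explicit heterozygous-to-missing toggle applied
before window correction. Segregation distortion is a 1-df chi-square on
homozygous parental-origin counts against 1:1 (F1DH) or 3:1 (BC1DH),
removing markers with p < 0.005 in any family with at least 10 informative
calls (smaller families are skipped with a warning).

**Sliding-window correction.** Each SNP's window spans 15 consecutive SNPs
centred on it, truncated at chromosome ends. The window is called P1 when
the P1 count strictly exceeds 11/15 of the non-missing calls ("over 11:4"
read strictly: with 15 informative calls P1 needs ≥ 12), P2 symmetrically,
heterozygous in between (the boundary exactly at 11:4 is heterozygous).
Missing calls are excluded from the counts; heterozygous calls count
toward neither parent but are corrected inside homozygous windows. Because
corrections change the counts of overlapping windows, the scan repeats to
a fixed point, which makes the operation idempotent by construction.
Breakpoints are recorded where consecutive homozygous window calls switch
parent, at the midpoint between the flanking SNPs; the fragments between
breakpoints are bins. True segments shorter than one window are beyond
the method's resolution and are absorbed — on error-free data the
corrected calls equal the input exactly wherever all true segments are at
least one window long.

**Projection.** Within each progeny bin all markers receive the source
parent's allele, filling both missing calls and within-family monomorphic
loci (both parents share the allele there). The merged matrix covers the
union of loci polymorphic in at least one family. Numeric coding maps the
major allele to +1 and the minor to −1 (ties to the reference allele);
the per-marker mean is then 1 − 2·MAF.

## Population structure

IBS distance is the mean allele-sharing mismatch over pairwise-complete
markers. Neighbor joining is delegated to scikit-bio (exact on additive
matrices); genotype PCA is a column-centred SVD; LD decay averages
squared Pearson correlations of numeric codes per physical-distance bin,
smooths isotonically, and interpolates the distance where the curve
crosses r² = 0.2. r² on numeric codes is the natural choice for
homozygous DH lines, where the genotype is the haplotype.

## Trial mixed models

Both trial models are fitted by REML. The engine absorbs the
line-by-environment interaction analytically: within a cell of n plots the
covariance is `sigma_GE^2 J + sigma_j^2 I`, whose inverse and determinant
are closed form, so the mixed-model-equations matrix contains only the
fixed effects (intercept/lines, sum-to-zero environment and
replicate-within-environment contrasts) plus genotypes and blocks. One
likelihood evaluation is a few sparse products and a dense Cholesky of a
few-hundred-dimensional matrix, and the profile REML is maximised
numerically over the log-variances with bounded L-BFGS-B.

Numerical choices: the response is standardized internally (location and
scale restored afterwards), which makes fits invariant to trait units;
numerically invalid parameter points return a finite sloped penalty rather
than a constant cliff, so line searches can back out; starting values come
from within-cell moment estimators with the remainder split evenly; if the
optimizer fails to move, two alternative starts are tried and the best
criterion wins. Variances are parameterized on the log scale, so negative
estimates cannot occur (boundary estimates come back as ~1e-8 of the
phenotype variance). Replicates are fixed and blocks random, the usual
treatment for augmented alpha designs. Residual variances are free per
replicate within one environment and free per environment across
environments, mirroring how the two error distributions differ between
the single- and multi-environment analyses.

Cullis heritability is `H² = 1 − v̄ / (2 sigma_G^2)` with `v̄` the mean
prediction-error variance of genotype-BLUP differences taken from the
inverse coefficient matrix. The outlier razor studentizes conditional
residuals with their exact variances `diag(R − W C⁻¹ W')` (the interaction
expanded explicitly for this one computation), applies the leave-one-out
t-transformation by default ("external"; an "internal" switch skips it),
and removes records beyond 2.8 in a single pass. LSD letters share a
letter iff the mean difference is below `t(1−α/2, df)·sqrt(2·MSE/n)`,
assigned greedily from the largest mean.

## Finlay–Wilkinson regression

The model `y_ij = mu + g_i + (1 + b_i) h_j + e_ij` with
`g ~ N(0, K sigma_g^2)`, `b ~ N(0, K sigma_b^2)`, `h ~ N(0, I sigma_h^2)`
is solved by Gibbs sampling. The kinship `K = M M'/m` on +1/−1 codes has
unit diagonal by construction; its eigendecomposition makes the `g` and
`b` conditionals diagonal, so a sweep costs two small rotations.
Scaled-inverse-chi-square priors (df 4, scale from a quarter of the
phenotype variance) are weak; the default chain is 2,000 iterations with
1,000 burn-in — a desk-scale choice that already gives slope estimates
stable to <0.01 RMS between chains; production chains of 20,000/10,000 are
one argument away.

Identifiability: `h` is centred every sweep (the shift absorbed into `mu`
and `g`), and because the likelihood is invariant to the rescaling
`(1+b)/c, c·h`, every kept sample is reported on the classical convention
mean(1 + b) = 1. With an identity kinship and informative data the
posterior-mean slopes then agree with per-line least-squares
Finlay–Wilkinson estimates. The slopes are reported on this unit-mean
scale; analyses that report slopes on other scales are not comparable
without renormalisation. Non-linear plasticity is the log of the per-line
residual variance at the posterior means, with the residual sum of squares
divided by (n_env − 2) — the df left after the line's own intercept and
slope — and floored at 1e-12 before the log.

## Gene-region variance partition

SNPs are assigned to exactly one of six categories with precedence
CDS > 5′UTR > 3′UTR > 2 kb upstream > 2 kb downstream > intergenic;
flanks are measured strand-aware from the gene boundaries, genes without a
strand contribute no flanks, and a SNP upstream of one gene and
downstream of another is resolved promoter-proximal (a flag flips this).
One kinship `K_c = M_c M_c'/m_c` per non-empty category enters
`y = X beta + Σ_c xi_c + e` with population indicators as fixed effects.
Each `xi_c` is sampled in its kernel's eigenbasis (diagonal conditionals);
variance priors are scaled-inverse-chi-square with df 5 and prior mean set
to one tenth of an even split of the phenotype variance — weak enough that
a pure-noise phenotype yields a phenotypic proportion near zero while a
planted h² = 0.5 signal is still recovered. Genetic shares
`sigma_c^2 / Σ sigma^2` sum to one by construction.

## G-by-E association scan

Single-phenotype scans use the classical Q+K model: six genotype PCs as
covariates, polygenic covariance `K sigma_g^2 + I sigma_e^2` estimated
once on the marker-free null model and reused for every marker
(population-parameters-previously-determined), and t-distribution
p-values with n − p − 1 df.

The stacked scan requires a complete line × environment BLUE table.
Ordering records environment-major, the covariance
`sigma_g^2 (J ⊗ K_g) + sigma_GE^2 (I ⊗ K_g) + sigma_e^2 I` is diagonal in
the basis `F ⊗ U` (F orthonormal with first column 1/√E, U the
eigenvectors of K_g), so the three-variance REML costs one pass over n·E
scalars per evaluation and each marker test is a handful of small dot
products: the main column is the marker codes constant across
environments, the interaction columns are the codes times an orthonormal
sum-to-zero basis, so `gamma` is exactly the environment-average effect
and the per-environment GGE effects `gamma + delta_j` average back to
`gamma`. `gamma` is tested by a 1-df Wald chi-square, `delta` jointly with
n_env − 1 df, and each GGE effect by a 1-df Wald test. The K_GE
construction (K_g within environment, zero across) is the block form of
the main kernel restricted to shared environments.

QTL intervals: the most significant remaining marker becomes the lead
(ties to the smaller position), r² is computed to every marker within
11 Mb on the chromosome, the interval extends left and right until r²
first drops below 0.2, and significant markers inside the interval are
claimed. Pleiotropy merges intervals that overlap or whose peaks are
within 1 Mb (transitive closure); candidate genes are all gene models
whose 1-based closed span intersects the interval (BED exports convert to
0-based half-open).

## Genomic prediction

The prediction model is the stacked kernel model without marker columns,
with environment and population indicators as fixed effects, fitted by
REML + BLUP through the same diagonalization; predictions for unobserved
lines come from kernel rows against `V⁻¹(y − X beta)`. Because
`sigma_GE^2` sits on the boundary of its parameter space, small spurious
positive estimates under a no-interaction truth would add pure noise to
the G-by-E model's predictions; `fit_gblup` therefore keeps the
interaction component only when it improves −2 log REML by more than the
5% point of the boundary null (0.5·chi²₀ + 0.5·chi²₁, threshold 2.706),
and reduces to the main model exactly otherwise. CV2 masks whole lines:
in each replicate 70% of the lines train the model and the other 30% are
predicted in every environment; predictive ability is the per-environment
Pearson correlation between observed and predicted values, and the two
models are compared per environment by a paired two-sided t-test over
replicates (default 50 at desk scale; 200 matches common practice).

## Problem sizes

The test-suite and acceptance-script defaults are chosen for a laptop:
234 lines × 300–1000 markers, 7 environments, 2 replicates; 50 replicates
for variance-recovery and CV2 studies, 25 for scan power and interval
coverage, 20 for the region partition; MCMC chains 2,000/1,000. All are
function arguments.

## Known limitations

- The stacked scan and GBLUP require complete line × environment tables;
  incomplete designs need per-environment BLUEs first (which is how the
  pipeline produces them).
- The interaction variance in the joint trial model is exchangeable
  (homogeneous across environments); structured interaction (for example
  slope-driven) is partially absorbed into per-environment residuals.
- Scan p-values are asymptotic (Wald/t under estimated variance
  components); the suite checks calibration empirically at n = 234.
- The window corrector cannot recover true double crossovers spanning
  fewer markers than one window.
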