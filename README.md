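# gxemap

Genetic dissection of genotype-by-environment interaction (G-by-E) in
multi-family biparental doubled-haploid (DH) populations.

Breeding programs evaluate the same inbred lines in several
macro-environments — combinations of year, location, and treatment (for
example soil-phosphorus level) — and the interesting biology is often not
the average performance but how performance *changes* across those
environments. `gxemap` implements the full analysis chain for such trials
as an importable Python library:

- **synthetic data** (`gxemap.simulate`) — multi-family DH/BC1DH meiosis
  on a genetic map (Haldane model), genotyping-noise injection, and
  augmented-alpha multi-environment trials with replicated checks and a
  complete truth ledger;
- **genotype pipeline** (`gxemap.genotypes`) — MAF/missing/heterozygosity
  and mapping-quality filters, per-family segregation-distortion tests,
  15-SNP sliding-window error correction with breakpoint/bin calling,
  parental-genotype projection, and +1/−1 numeric coding;
- **population structure** (`gxemap.popstruct`) — identity-by-state
  distances, neighbor-joining trees, genotype PCA, LD-decay profiles;
- **trait models** (`gxemap.traits`) — studentized-residual outlier razor,
  per-environment and across-environment mixed models with heterogeneous
  residual variances, BLUEs, variance components, Cullis heritability,
  and LSD letter displays;
- **plasticity** (`gxemap.plasticity`) — kinship-augmented
  Finlay–Wilkinson regression giving linear plasticity (slopes) and
  non-linear plasticity (log residual variance);
- **region variance** (`gxemap.regions`) — SNP assignment to six
  gene-region categories from GFF3 gene models and a six-kernel Gibbs
  decomposition of genetic variance;
- **G-by-E GWAS** (`gxemap.gwas`) — Q+K scans, decomposition of each
  marker effect into a constant main effect and environment-specific
  interaction effects, per-environment GGE effects with Wald tests,
  Benjamini–Hochberg FDR, LD-delimited QTL intervals, pleiotropy merging,
  candidate-gene overlap;
- **genomic prediction** (`gxemap.predict`) — multi-environment GBLUP
  with and without a G-by-E kernel, assessed by the CV2 scheme
  (whole lines masked from every environment).

## The models

Plot-level phenotypes follow the across-environment mixed model

```
y_ijm = mu + G_i + E_j + GE_ij + R_m(E_j) + B_n(E_j R_m) + e_ijm,
e_ijm ~ N(0, sigma_j^2),
```

with genotype, interaction, and blocks random for variance components
(ratio `sigma_GE^2 / sigma_G^2` and Cullis `H^2 = 1 − PEV̄ / 2 sigma_G^2`)
and genotype fixed for BLUEs. Linear plasticity comes from the
Finlay–Wilkinson regression

```
y_ij = mu + g_i + (1 + b_i) h_j + e_ij,     g, b ~ N(0, K sigma^2),
```

where `(1 + b_i) = 1` is average environmental sensitivity and `0` is no
response. The G-by-E scan decomposes each marker effect in stacked
per-environment BLUEs,

```
y = X beta + Z_k gamma_k + W_k delta_k + u + u_GE + e,
```

with `gamma_k` the constant main effect (Wald chi-square, 1 df), `delta_k`
environment-specific effects summing to zero (chi-square, n_env − 1 df),
and two polygenic kernels: `u ~ N(0, K_g sigma_g^2)` shared across
environments and `u_GE ~ N(0, K_GE sigma_GE^2)` with `K_GE = K_g` within an
environment and 0 across. Removing `u_GE` from the same model gives the
main-effect GBLUP used for prediction.

## Worked example

`examples/` contains one narrative script per capability. For instance,

```
python examples/04_trait_models.py
```

simulates a 234-line trial (planted `sigma_G^2 = 11.17`,
`sigma_GE^2 = 5.13`, mean plot-error variance 6) and prints

```
razor removed 23 of 3612 plots
sigma_g2 = 11.73 (truth 11.17), sigma_ge2 = 5.42 (truth 5.13)
ratio sigma_ge2/sigma_g2 = 0.46, Cullis H2 = 0.91
```

— the variance components are recovered, their ratio is the standard
measure of how much interaction a trait carries relative to its genetic
signal, and the heritability matches the designed 0.90. Similarly,

```
python examples/08_prediction.py
```

compares the two prediction models under strong interaction
(`sigma_GE^2 = sigma_g^2`) and shows the G-by-E model winning in all seven
environments (mean predictive ability 0.74 vs 0.58), quantifying the value
of modelling interaction when predicting lines never tested in any trial.

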