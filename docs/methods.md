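# Methods

## The model

`aseqtl` detects allele-specific eQTLs (aseQTLs) with a hierarchical
Poisson mixed model (HPMM) fitted to per-subject allelic expression
counts:

```
y_ij | b_i, eps_ij  ~  Poisson( K_ij * exp(mu + X_ij * beta + C_ij' * gamma + b_i + eps_ij) )

b_i     ~  N(0, var_b)       subject-level random intercept
eps_ij  ~  N(0, var_eps)     observation-level random effect
```

- `y_ij` is the j-th count of subject i — either an allele-specific count
  (one of the two alleles of a heterozygote) or the subject's total count
  (homozygotes, or subjects whose allelic split is unobservable).
- `K_ij` is the exposure offset: the library size `l_i` for a total
  count, `l_i / 2` for each allelic count of a heterozygote (each allele
  is transcribed from one of two chromosome copies).
- `X_ij` codes the tested allele. The subject intercept `b_i` pairs the
  two allelic observations of a heterozygote, so `beta` is identified
  both *within* heterozygous subjects (allelic imbalance) and *between*
  genotype groups (total-expression differences). `eps_ij` absorbs
  extra-Poisson noise (overdispersion).
- The aseQTL test is a Wald test of `beta = 0`; a likelihood-ratio test
  against the no-`beta` null fit is also provided.

### Allele-pattern coding (`aseqtl.design`)

**Exonic mode** — the tested SNP is itself transcribed. A heterozygote
contributes two paired observations: the effect-allele count with
`X = 1` and the other-allele count with `X = 0`, offsets `l/2` each.
A homozygote contributes its total count with `X = 1` (effect/effect)
or `X = 0`, offset `l`.

**GWAS (haplotype) mode** — the tested SNP is not transcribed; allelic
counts are read through a transcribed proxy SNP. Only subjects
heterozygous at *both* SNPs ("double heterozygotes") reveal the
GWAS-allele-specific counts, via phase: the haplotype carrying the
effect GWAS allele contributes the count of its phased exonic allele
with `X = 1`, the other haplotype with `X = 0` (offsets `l/2`).
Every other subject contributes one genotype-level observation with
dosage coding `X in {1, 0.5, 0}` and offset `l`. Unphased double
heterozygotes are an error; analyses with fewer than 3 double
heterozygotes are flagged (`low_double_het`).

An optional binary group label `D` extends the linear predictor with
`alpha * D + delta * X * D`; the Wald test of `delta = 0` detects a
differential (group-specific) allelic effect.

### Estimation

The marginal likelihood integrates the random effects per subject; the
integral factorizes over subjects with latent dimension 1 (single
observation: combined variance `var_b + var_eps`) or 2 (heterozygote
pair: covariance `[[A, B], [B, A]]` with `A = var_b + var_eps`,
`B = var_b`). Each factor is evaluated with a Laplace approximation
around the per-subject conditional mode, found by a damped Newton
iteration that is vectorized across subjects and warm-started between
outer iterations. Without the observation-level effect a heterozygote
pair reduces to a single shared latent intercept.

Outer optimization is L-BFGS-B over `(mu, beta, gamma, log var_b,
log var_eps)` with `3-point` finite-difference gradients, followed by a
bound-aware damped-Newton polish of all parameters. Wald standard
errors come from the finite-difference Hessian of the profile objective
in the fixed-effect block at the estimated variance components.

Numerical choices that matter:

- **Saturated-likelihood shift.** The objective is shifted by the
  saturated Poisson log-likelihood so its magnitude is O(deviance)
  rather than O(sum y log K). Without the shift, finite-difference
  gradients are dominated by floating-point cancellation and the polish
  cannot reach the 1e-6 invariance level the tests demand.
- **Tight inner tolerances.** The inner Newton solves to step sizes
  below 1e-13 so that warm-start hysteresis in the Laplace modes does
  not alias into the outer finite-difference gradients.
- **Variance floor and auto-drop.** Log-variances are bounded in
  [log 1e-10, log 1e4]. If the `eps` variance estimate collapses below
  1e-8 the model is refitted without it and labelled `hpmm_no_eps`;
  this keeps the Wald SE well-defined when the data carry no
  overdispersion.
- **Convergence fallback.** L-BFGS-B occasionally reports an abnormal
  line search while already at the optimum; convergence is then decided
  by the measured bound-aware gradient (max |g| < 1e-3).

Exact invariances used as correctness oracles: relabelling the effect
allele (`X -> 1 - X`) flips the sign of `beta`; scaling all offsets by a
constant `c` leaves `beta` and the variances unchanged and shifts `mu`
by `-log c`. Both hold to 1e-6 (typically ~1e-9) on refined fits. With
both variance components pinned to zero the fit reproduces a plain
Poisson GLM (statsmodels) in coefficients, SEs and log-likelihood.

### Relation to binomial models

Conditioning a heterozygote's Poisson pair on its total count cancels
`mu`, `b_i` and the offsets: the effect-allele count is
`Binomial(n_i, expit(beta + eps_i1 - eps_i2))`. The HPMM restricted to
heterozygotes is therefore an overdispersed binomial (logit) model —
without `eps` its `beta` estimate is exactly the pooled log-odds. The
package ships a beta-binomial comparator (`fit_betabin`,
parameterized by mean `expit(beta)` and intraclass correlation `rho`,
built on `scipy.stats.betabinom`) which behaves near-identically to the
heterozygote-only HPMM in simulations. The full HPMM additionally uses
homozygous subjects' total counts, which is where its power advantage
comes from.

## Quality control (`aseqtl.io_qc`)

- Imputed genotypes are kept only with imputation R² strictly above
  0.96 (directly genotyped calls bypass the filter) — phasing errors in
  marginal imputations would corrupt haplotype-based allele assignment.
- Imputed genotypes are cross-checked against RNA-seq allele counts when
  coverage exceeds 20 reads: the minor/major count ratio must be above
  2% for a heterozygote and at most 10% for a homozygote, otherwise the
  call is overridden by the RNA-seq-implied genotype.
- Exonic loci with mean raw count below 2 across subjects are dropped.
- Candidate (GWAS SNP, gene) pairs are formed within a ±500 kb window
  around the transcription start site (boundary inclusive).

## UMI-level quantification (`aseqtl.umi_ase`)

For droplet snRNA-seq, allele counts are numbers of unique UMIs: within
one cell and locus, reads not assigned to a transcript are ignored; a
UMI whose reads disagree on the allele is discarded; surviving UMIs are
collapsed at Hamming distance ≤ 1 (directional — absorbed into the
best-supported group, ties broken lexicographically), and a collapsed
group mixing alleles is discarded. Counts are aggregated into
pseudo-bulk per (subject, cell type, locus); the default library size is
the subject × cell-type total UMI count.

## Interpretation (`aseqtl.interpret`)

P-values across tested pairs are adjusted with Benjamini–Hochberg FDR.
A significant GWAS-SNP association is classified by comparing it with
the exonic SNP's own association and the two SNPs' LD:

1. the exonic SNP is *less* significant → the GWAS SNP (or a variant it
   tags) is the better candidate;
2. otherwise, genotype-dosage correlation |r| > 0.8 → statistically
   indistinguishable signals;
3. otherwise → the allelic signal points away from the GWAS SNP.

Two correlations are distinguished. The *genotype* correlation is the
Pearson correlation of dosages over all subjects. The *allelic*
correlation is computed across the phased chromosomes of double
heterozygotes only — with rare alleles it can be ±1 (all double
heterozygotes in a sample carry the same phase configuration, e.g. when
the minor–minor haplotype is absent) even though the population LD is
negligible. A strong allelic association at the exonic SNP therefore
need not implicate the GWAS SNP.

## Simulation defaults (`aseqtl.simulate`)

The reference study design: 500 subjects, Hardy–Weinberg genotypes,
`var_b = 1`, `var_eps = 0.5`, effect sizes 0–0.3, MAFs 0.1–0.4,
tests at the 5% level. The baseline `mu` is chosen so the *expected*
allelic count is `mean_count` (default 50) at library size 1e6 after the
lognormal correction `mu = log(mean_count / (l/2)) − (var_b+var_eps)/2`;
the count depth is a package choice meant to represent a well-expressed
gene in bulk RNA-seq, and power results should be read as relative
comparisons between methods, not absolute predictions for a particular
dataset. All methods in a power study are evaluated on the same
replicate datasets; replicates where a method fails to converge are
excluded from that method's denominator and reported (`n_failed`).
Per-cell streams are spawned from a single `SeedSequence`, so results
are reproducible for a given seed and independent of the grid shape.

Generator realism limits: counts are drawn from the model itself (no
mapping bias, no reference-allele bias, no genotyping error), genotypes
are in perfect HWE, and library sizes are constant across subjects.
These are deliberate: the simulations test the statistics, not the
upstream bioinformatics.
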