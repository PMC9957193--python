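# Methods

## Model and assumptions

The response is the vector of adjusted hybrid phenotypes (BLUEs) across
environments (years). All models are Gaussian multi-kernel mixed models

y = Xβ + Σ_k u_k + ε,  u_k ~ N(0, σ²_k K_k),  ε ~ N(0, σ²_ε I),

where each K_k is a record-level covariance kernel and X holds the
intercept plus optional parental covariates. The full predictor (family B)
carries seven random terms: environment main effects (modelled as random
with their own variance σ²_E; a flat-prior/fixed-effect option exists, the
intercept is always flat), male and female GCA, hybrid SCA, and three
Hadamard-product genotype×environment interactions. Families A/C/D delete
or substitute terms:

* A — same structure as B with identity kernels in place of G_M, G_F, H
  (pedigree-free, marker-free);
* C — environment + hybrid effect + hybrid×environment only, identity
  kernels;
* D — as C with genomic kernels.

Assumptions worth making explicit: parents come from two distinct pools
(heterotic groups), so male and female GCA are separate effects with
separate kernels; parents are inbred, so hybrid genotypes are determined by
their parents and hybrids need never be genotyped; traits are analysed one
at a time, with cross-trait information entering only through the parental
covariates; residuals are homoscedastic across environments.

### Kernels

* GRM: G = W W′/p with W the column-centered dosage matrix divided by the
  per-column **population** (denominator-n) standard deviation. This makes
  mean(diag G) exactly 1, which the code asserts to 1e-10; sample-sd
  standardization is available via `population_sd=False`. Kernels are not
  further rescaled.
* SCA kernel: H[i,j] = G_M[m_i,m_j]·G_F[f_i,f_j] — the observed-cross
  sub-matrix of the Kronecker product G_M ⊗ G_F. Only the crosses in the
  pedigree are materialized; at the scale this package targets (hundreds
  of females × tens of males) the full Kronecker product would be wasteful
  and is only ever formed inside tests as a brute-force oracle.
* Record expansion: (Z K Z′)[r,s] = K[entity(r), entity(s)], implemented by
  label indexing rather than explicit incidence matrices.
* Interactions: Hadamard products of an expanded genetic kernel with the
  expanded environment-block kernel Z_E Z_E′; entries between records in
  different environments are exactly zero, and the product is PSD by the
  Schur product theorem.

In the non-genomic families every kernel, including the one inside the
hybrid×environment interaction, is identity-based. The variant in which
that interaction keeps the genomic H while the main hybrid effect is
identity (`literal_uh=True` on `assemble_model`) is retained because both
readings of the model family definitions circulate; the identity-based
default keeps "non-genomic" models genuinely free of marker information.

### Parental covariates

Per trait t, the additive covariate is the mid-parent value
(P_M,t + P_F,t)/2 and the dominance covariate is |P_M,t − P_F,t|/2 (half
the parental divergence, which tracks the scope for heterotic deviation).
The alternative |P_M,t + P_F,t|/2 is available as `half_abs_sum`; it is a
rectified rescaling of the additive column and is kept only for
comparability, since published descriptions of this construction are
ambiguous between the two. Mode `C` emits the two columns of the target
trait, mode `AC` two columns for every configured trait (6 columns for 3
traits). Columns are centered (the intercept absorbs their mean) but not
variance-scaled, because their coefficients carry a flat prior and scaling
would only relabel the estimates.

## Marker QC

Three steps, strictly ordered: (1) drop markers with missing fraction ≥
`max_missing_frac` (default 0.15 — "keep if strictly below"); (2) impute
remaining missing cells with the column's observed mean; (3) drop markers
with minor allele frequency < `min_maf` (default 0.05), computed from the
post-imputation column mean as min(q, 1−q), q = mean/2. Mean imputation
leaves column means unchanged, so pre- vs post-imputation MAF is the same
quantity; the post-imputation convention is the one the code can assert on
its own output. The pipeline is idempotent and never changes the line set.

## Fitting: Gibbs sampler

Each kernel is eigendecomposed once, K = U D U′ (eigenvalues below
1e-10 × max truncated), and the random effect re-parameterized as
u = U D^{1/2} δ with δ ~ N(0, σ²_k I). Because U has orthonormal columns,
the full conditional of δ is diagonal, so one sweep costs O(n·r_k) per
term. Fixed effects are updated coordinate-wise under a flat prior;
exact-zero columns are skipped (their coefficient stays 0), which makes
the sampler robust to degenerate covariate columns. Variances carry
scaled-inverse-χ² priors with df = 5 and scale set so the prior mode
equals an equal split of 50% of var(y) across the random terms (the
remaining 50% to the residual) — the conventional weakly-informative
default for this model class. Defaults are 12,000 iterations, 2,000
burn-in, thinning 5; the CV experiments in the test-suite and acceptance
script use 1,200/400/4, which at the simulated problem sizes (~180 records)
gives MSE estimates stable to well under the effect sizes being compared.

Masked responses (the CV test sets) are treated as missing data and
imputed each sweep from the current predictor plus residual noise; the
reported prediction is the posterior mean of the linear predictor at the
masked record, which equals the posterior mean of the imputed values in
expectation but with less Monte-Carlo noise. Divergent (non-finite)
variance draws abort with diagnostics. Identical inputs and seed reproduce
every output bit-for-bit.

A closed-form GLS/BLUP solver (`blup_oracle`) provides the independent
check: V = Σ σ²_k K_k + σ²_ε I (with a 1e-8 diagonal jitter against
singularity), β̂ by generalized least squares on the training block, and
test predictions via the kernel cross-blocks. With variances held fixed at
truth, sampler predictions agree with this oracle to within 0.05·sd(y) at
10,000 iterations in the test suite.

## Cross-validation and comparison

CV1 ("untested lines in tested environments"): hybrids — not records —
are shuffled with a seeded generator and dealt round-robin into k = 7
folds (sizes differ by ≤ 1). Holding out a fold masks *all* records of its
hybrids in every environment. MSE is pooled over test-record squared
errors per environment and globally; the unweighted mean of per-fold MSEs
is also reported (`fold_mean_mse`) since "average over folds" is the other
defensible reading, but the pooled version is the primary statistic
because it weights every record equally. Global MSE therefore equals the
record-count-weighted mean of per-environment MSEs. All models in a
comparison share one fold partition (paired design), asserted through a
hash of the partition carried in every report. RE = MSE_ref/MSE_cand;
gains are conventionally displayed to 1 decimal and REs to 3, with
half-up decimal rounding in `mean_percent_gain` so that printed
three-decimal REs yield exactly reproducible one-decimal summary gains.

## Synthetic data generator

The generator emulates the structure of a multi-year two-pool hybrid wheat
trial series: a small male pool (default 6) and a larger female pool (40),
fully homozygous (dosages 0/2; a heterozygous option exists), 300 shared
markers with allele frequencies ~ U(0.1, 0.9) and every column polymorphic
within each pool; 3 environments of 60 hybrids whose consecutive-year sets
overlap by 30%; 3 traits whose marker effects are drawn with cross-trait
correlation 0.5. GCA values are W α per pool; SCA and the three
interaction effects are drawn from the model's own kernels (H, and the
per-environment kernel blocks, which is exactly the Hadamard structure),
so parameter recovery by the sampler is a well-posed exercise; an iid
alternative can be emulated by passing identity-like configurations.
Parental phenotypes are each parent's own additive value plus N(0, 0.05)
noise — parental BLUEs from replicated trials are high-precision, and this
is what makes mid-parent covariates informative.

Default variance components (unit response scale): σ²_E = 1.0,
σ²_M = σ²_F = 0.5, σ²_h = 0.25, σ²_ME = σ²_FE = σ²_HE = 0.15, σ²_ε = 1.0 —
environment dominating, additive GCA the main genetic signal, moderate SCA
and G×E, and a broad-sense record-level heritability around 0.45, typical
of yield-like traits from adjusted means. Every realized effect vector is
rescaled so its population variance equals its component exactly; this
trades a little distributional purity for exact, testable targets at small
pool sizes. Residuals are left unscaled. Missing marker data for QC
testing is injected post hoc (`corrupt_markers`) with its own rate and
seed.

What the generator does **not** emulate: linkage disequilibrium and
genetic maps, selection and drift across years, heterosis physiology,
environment-specific residual variances, and real allele-frequency
spectra. Passing tests on this generator therefore demonstrate the
statistical machinery (kernel algebra, sampler correctness, CV
bookkeeping, the qualitative value of parental covariates under the
model's own assumptions), not performance claims about any real breeding
program.

## Problem sizes and replication in the checks

The replicated CV study in the acceptance script and test suite uses the
default generator (144 unique hybrids, 180 records per trait), 7 folds,
10 replicates, and the non-genomic families A and C with covariate modes
none/`_C`/`_AC` — the families for which the covariate effect is largest
and cleanest to measure. The redundancy check (`_C` vs `_AC` when the
extra traits carry no signal) sets the trait genetic correlation to zero,
so the four extra covariate columns are pure noise for the target trait;
the expected outcome is RE slightly below 1 (a small overfitting cost of
four free coefficients at ~150 training records), and the observed mean is
within ±0.05 of 1. Under the *default* correlated configuration the `_AC`
mode pays a similar small cost relative to `_C` — consistent with the
empirical finding that correlated-trait covariates add little once the
target-trait covariate is present.

## Numerical choices and degenerate inputs

* Eigenvalue truncation at 1e-10 × max; kernels failing PSD by more than
  1e-8 relative are rejected.
* GRM construction refuses monomorphic columns by name (QC first) and
  missing values.
* BLUP oracle jitter: 1e-8 on the training-block diagonal.
* Constant responses are handled by falling back to a unit prior scale.
* Ties in fold sizes are resolved by the shuffled round-robin order;
  fold assignment is a pure function of (ids, k, seed).
* Duplicate line/marker/hybrid ids, ragged files, unknown parents and
  unmapped records are hard errors that name the offending ids.

## Design choices where the design was open

* **Environment effects random by default** with variance σ²_E, matching
  the distributional statement of the model; a fixed-effect treatment is a
  one-line option at assembly.
* **Run configuration** lives in CLI options echoed into a `manifest.json`
  (with seed, package version and input checksums) rather than a separate
  config-file format; the manifest is sufficient to reproduce a run.
* **Pooled vs fold-averaged MSE** — both computed, pooled primary (above).
* **Dominance covariate rule** — divergence-based default, literal
  alternative flagged (above).
* **Sampler settings for CV** — scaled to the simulated problem sizes so a
  full 12-model comparison is an interactive-scale computation; accuracy
  assertions in the tests use longer chains.

## Known limitations

* Single-trait likelihoods only; cross-trait information flows solely
  through covariates.
* No BayesB/LASSO-type marker priors; every term is Gaussian with one
  variance.
* The Gibbs sampler eigendecomposes each record-level kernel, O(n³) per
  term once per model; fine for thousands of records, not for hundreds of
  thousands.
* VCF import covers biallelic GT records only (multiallelic records are
  counted and skipped); no phasing, INFO or PLINK/HapMap support.
* Identity-kernel families treat every untested hybrid as exchangeable;
  their CV1 predictions for new crosses rely entirely on parental terms
  and covariates, which is the intended contrast, not a bug.
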