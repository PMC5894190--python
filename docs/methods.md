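# Methods

## Model

For one trait, records indexed by (individual, year) follow

Y = Xb + Z1 a + Z2 d + Z3 i + Z4 aY + Z5 dY + Z6 iY + e,

where year is a fixed factor (intercept plus reference-level contrasts;
the first year is the reference — all reported quantities are
coding-invariant), Z1–Z3 are records × individuals incidence matrices
and Z4–Z6 records × (individuals · years) incidence matrices in
year-major order. The genetic terms are zero-mean Gaussian with
covariances σ²a·Ga, σ²d·D, σ²aa·Gaa and, for the interactions,
I_Y ⊗ K σ², i.e. independent redraws of the same kernel-structured
effect per year. The residual is a repeated measure: R = I_ind ⊗ Σe,
with Σe a Y × Y matrix. The default residual structure is a homogeneous
variance with free year-pair correlations (3 free correlations for 3
years); this was preferred over heterogeneous per-year variances
because the variance decomposition is reported as a single error share,
but a heterogeneous variant (per-year variances plus covariances) is
available via `residual="heterogeneous"`, and `"independent"` drops the
correlations.

### Kernels

With dosages m_ij ∈ {−1, 0, 1} and p_j the frequency of the positively
counted allele:

* VanRaden additive: H_ij = m_ij − 2(p_j − 0.5),
  Ga = HH' / (2 Σ_j p_j (1 − p_j)).
* Su dominance: Z_ij = 1 − 2p_j(1−p_j) for heterozygotes and
  −2p_j(1−p_j) for either homozygote,
  D = ZZ' / Σ_j 2p_j(1−p_j)(1 − 2p_j(1−p_j)).
* Epistasis (additive × additive): Gaa = Ga ∘ Ga, taken before any
  bending.

Frequencies are estimated from the curated, imputed matrix. Genotype
curation removes individuals, then markers, exceeding 25% missingness,
then markers under MAF 0.05; the individual-first order is a fixed
convention (the filters commute only approximately). Missing calls are
imputed with the marker mean dosage rounded to the nearest legal call —
a deliberate, documented simplification appropriate for synthetic data
whose missingness is generated completely at random; haplotype-aware
imputation is out of scope. Rank-deficient kernels are bent by
eigenvalue clipping: eigenvalues below 1e−6 are raised to 1e−6 and the
matrix reconstructed. Clipping is the minimal-perturbation fix that
preserves eigenvectors and guarantees an invertible covariance for the
mixed-model equations; the clipping floor doubles as the PD margin.

### REML

All parameters enter V(θ) = Σ_k θ_k B_k linearly: each genetic variance
multiplies Z_t K_t Z_t', the residual variance multiplies I (or per-year
diagonals in the heterogeneous variant), and each year-pair residual
covariance multiplies a same-individual pair indicator (correlations
are recovered afterwards as c_pq / σ²e). The engine is
average-information REML: score
−½[tr(P B_k) − y'P B_k P y] and AI matrix ½ (B_j P y)' P (B_k P y),
with P the REML projection. Updates are damped by step halving; when no
AI step improves the likelihood, an EM-REML step
θ_k ← θ_k + θ_k² (y'P B_k P y − tr(P B_k)) / q_k is taken for the
variance parameters (covariances held for that iteration). When neither
family of steps improves the likelihood beyond numerical resolution the
point is accepted as a (possibly boundary-constrained) maximum.

Constraints: variances are pinned at a floor of 1e−8 × the
fixed-effect-adjusted phenotypic variance; a parameter pinned three
consecutive iterations is profiled out, but is released if its score
turns positive again (premature profiling otherwise biases the
remaining components). Residual covariances are shrunk back toward zero
whenever the implied Σe leaves the positive-definite region. Starting
values split the adjusted phenotypic variance equally over the included
variance parameters, with correlations starting at 0.1; using the
adjusted (not raw) variance makes the optimizer invariant to year-mean
shifts.

Convergence requires both a relative log-likelihood change below
`loglik_rtol` (default 0.002) and all free parameters changing less
than `param_rtol` (default 1%) — deliberately modest defaults matching
common mixed-model practice; oracle-agreement tests tighten them to
1e−8/1e−4. The reported log-likelihood includes the −(N−f)/2·log 2π
constant.

BLUPs are recovered as u_t = σ²_t K_t Z_t' V⁻¹ (y − Xb̂), which equals
the Henderson mixed-model-equation solution (asserted in tests by
solving the MME independently). Unphenotyped individuals are carried in
the kernels, contribute no design rows, and receive predictions through
the kernel. The extended hat matrix is computed as W C⁻¹ W' with
C = W'R⁻¹W + blockdiag(0, G⁻¹) and W = [X Z]; the influence flag
(diagonal > 2 × mean of nonzero diagonal) is invariant to the overall
residual scale, which is why the plain (not R⁻¹-postmultiplied)
convention is acceptable and documented here.

A spectral single-kernel REML (eigendecomposition of K, profiled
residual variance, bounded scalar search over σ²g/σ²e) is shipped as an
independent second algorithm for cross-checking additive-only fits; it
is never used as the fitting path.

## Model comparison and heritability

The ladder holds the residual structure fixed and drops variance
components from the full ADI model: the three single-interaction drops
(df 1), three main-plus-interaction pair drops (df 2), the
main-effects-only model (df 3), three single-main-plus-interaction
models (df 4) and three single-main-effect models (df 5) — 13 reduced
models. Because dropped variances sit on the boundary, the LRT
statistic max(0, 2ΔlogL) is referred to the equal-weight binomial
chi-bar-square mixture Σ_k 2^−q C(q,k) χ²_k, with q the number of
dropped parameters; the equal weights are the standard choice for
independent boundary parameters and are an assumption (the weights are
not derivable from the model ladder alone). Heritabilities use
h² = σ²a/T and H² = (σ²a+σ²d+σ²aa)/T with T the sum of all six genetic
components plus the residual, so the percentage table sums to 100 and
h² equals the additive percentage.

## Cross-validation

All schemes re-estimate the variance components on the training records
and score the Pearson correlation between kernel-propagated genetic
values (a+d+i) of held-out individuals and their observations adjusted
for the training fit's fixed effects, pooling one pair per record
across years. k-fold removes all years of a held-out individual at
once; folds are shuffled round-robin, sizes differing by at most one,
and every repeat's fold assignment is reproducible from the recorded
seed. Leave-family-out makes one fold per full-sib family.
Leave-year-out removes a calendar year; the held-out year's fixed
effect is inestimable from training, but since every held-out record
shares it, the Pearson correlation is unaffected and records are
adjusted for the intercept only.

Two properties of these schemes matter for interpreting results on
simulated data. First, fold-level accuracies within one simulated
population are strongly correlated (they share the population's noise
realization), so null-accuracy and accuracy-ordering summaries average
over replicate populations rather than repeats within one. Second, in
a correctly specified simulation leave-year-out is *easier* than
k-fold — the held-out individuals' other-year records remain in
training — so its signature under genotype-by-year variance is the
collapse of that advantage (and an absolute accuracy drop), not a fall
below the k-fold accuracy.

## Synthetic generator

The generator emulates the shape of a breeding-program reference set:
43 founders, 66 full-sib families of 7 (505 individuals), 1615 SNPs,
three trial years with the first year sparsest (default per-year
missingness 0.30/0.05/0.05 — assumed values; only the ordering, first
year sparsest, is given by the emulated setting). Founders are drawn in Hardy–Weinberg
equilibrium with marker allele frequencies uniform on (0.1, 0.5) and a
realized-MAF floor of 0.05; offspring are produced by Mendelian
gene-dropping at unlinked loci. Genetic effects are drawn directly from
the kernel-covariance multivariate normals, so the fitted model is
exactly correctly specified and parameter recovery is a clean test
surface. Default variance components follow a bloom-date-like
decomposition (a/d/aa/aY/dY/aaY/error =
0.332/0.108/0.175/0.112/0.042/0.021/0.211 on unit phenotypic variance)
with residual year correlations of 0.2 (assumed) and year means
10/12/11 (arbitrary, absorbed by the fixed effects). Fully
unphenotyped individuals can be injected via `n_unphenotyped` (off by
default — they exercise prediction, not estimation).

What the generator does *not* emulate: linkage disequilibrium and
linkage between markers (the model consumes only kernels, so unlinked
loci suffice for testing the pipeline, but LD-driven non-orthogonality
of the kernels in real arrays is not reproduced), selection or
assortative mating, explicit QTL architectures, and multi-trait genetic
correlations. Passing tests therefore demonstrate the estimation
machinery under a correctly specified model, not robustness to the
model misspecifications of real data.

## Problem sizes and numerical choices

Simulation-based checks use scaled-down populations chosen to keep the
whole suite quick while leaving each check statistically decisive:
parameter recovery runs 10 replicates at n = 300 (41 founders, 37
families of 7) with the default components; boundary-LRT calibration
runs 500 single-year replicates at n = 30; cross-validation checks use
n = 72 populations with additive-only models; heritability-inflation
runs 10 replicates at n = 150. With three correlated genetic kernels
and interaction terms that are nearly collinear with the correlated
residual, single-replicate component estimates are intrinsically noisy
(the likelihood has flat ridges); replicate means are the meaningful
recovery statistic.

Degenerate inputs: monomorphic markers are rejected at kernel
construction (zero VanRaden scale); an all-missing marker cannot
survive curation; simulating from a non-PD kernel raises an error
directing to bending; leave-one-out-style folds whose held-out records
cannot support a correlation (fewer than 3 records, or zero prediction
variance) contribute NaN and are excluded from fold averages. The
statistic of a reduced model whose converged likelihood exceeds the
full model's by numerical noise is clipped at zero.
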