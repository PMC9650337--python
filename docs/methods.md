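# Methods

## Model and hypothesis

Microbiome profiles are treated as compositions: for group g ∈ {1, 2}
and sample i, the observed relative abundances R_i^g lie in the open
simplex (all entries strictly positive after pseudo-count imputation,
rows summing to one). The centered log-ratio transform

    X_ij^g = log R_ij^g − (1/p) Σ_k log R_ik^g

maps each sample to the zero-sum hyperplane. The hypothesis tested is
equality of the CLR mean vectors, H0: μ_X¹ = μ_X². Because both mean
vectors sum to zero, equality of all p components is equivalent to
equality of the first p − 1; the primary statistic maximizes over the
first p − 1 components accordingly.

The latent abundance model behind the generator (and the motivation for
the CLR scale) is log-normal: log absolute abundances L ~ N(μ_L, Σ_L)
per group, A = exp(L), R the closure of A. Under this model the CLR data
are exactly the row-centered L, so CLR mean differences correspond to
log-fold changes of absolute abundances up to a common per-sample shift.

## The primary test and its calibration

Per component, the squared Welch-standardized mean difference is

    t_j = (n1 + n2) (x̄_j¹ − x̄_j²)² / σ̂_jj ,
    σ̂_jj = (n1+n2)/n1 σ̂¹_X:jj + (n1+n2)/n2 σ̂²_X:jj ,

with the biased 1/n_g variance estimators (no Bessel correction — the
calibration constants absorb the difference asymptotically, and the
printed estimator is implemented verbatim). T = max_{j ≤ p−1} t_j. As
n1, n2, p → ∞ the standardized statistic (T − shift)/scale is standard
Gumbel with

    scale = 2 − 1/log(p−1)
    shift = h_p + log 4 − log 4 / (2 log(p−1))
    h_p   = 2 log(p−1) − [log log(p−1) + log 4π]
            + [log log(p−1) + log 4π] / (2 log(p−1)).

P-values are computed in survival form, `−expm1(−exp(−t))`, so they
underflow only when t exceeds ~745; standardized values beyond ±700
trigger a warning. The decision rule uses the critical value
`scale·q_α + shift` with q_α = −log log (1/(1−α)) and the ≥ convention at
ties, which is identical to `p-value ≤ α`.

Accuracy of the closed form is excellent sooner than the asymptotics
suggest: for independent components the exact level of the nominal 5%
test at p = 100 is ≈ 0.049, and the acceptance suite measures a
Kolmogorov distance of ≈ 0.03 between the standardized null statistic and
the Gumbel law at p = 200, n1 = n2 = 300 (2,000 replications). The
approximation degrades for small p; the calibration refuses p < 3 and
warns for p < 10. Mid-range p-values (0.3–0.9) carry an approximation
error of up to ~0.05–0.08 at p = 100 relative to a label-permutation
reference; in the decision-relevant region (p ≤ 0.3) the two agree to
~0.01–0.02. Deciding at conventional α, the closed form and a
permutation calibration are interchangeable.

### Dropped component

The zero-sum redundancy means one CLR component must be excluded; the
package drops the *last* column in input order. The choice is
asymptotically immaterial but finite-sample values depend on column
order; `max_over_all=True` provides a diagnostic maximum over all p.

## Competing tests

- **MEC** (pooled max-type): per-component statistic
  `(n1 n2/(n1+n2)) (x̄¹−x̄²)²/σ̂_0:jj` with the pooled 1/(n1+n2) variance,
  maximum over all p components. Its originating formulation states no null law;
  the package calibrates it with the Gumbel-type limit of its source
  family — centering 2 log p − log log p, limiting law
  exp(−π^{−1/2} e^{−t/2}) — and offers a seeded label-permutation
  fallback (`calibration="permutation"`). Valid only under equal group
  covariances; quantifying its failure otherwise is a purpose of the
  harness.
- **MEC-Raw / MEC-Log**: the same pooled statistic applied to raw
  compositions R and to log R.
- **MEC-Oracle**: the pooled statistic granted access to the latent
  absolute abundances (simulation only; such data are unobservable in
  real studies). The statistic is applied on the log scale, log A = L,
  where the abundance model is Gaussian and the simulated mean difference
  lives. Applied to raw log-normal abundances instead, the max-type
  normal approximation fails outright (per-component sample means carry
  skewness on the order of e^{3σ²/2}/√n), which would make the benchmark
  meaningless; the log scale is the analysis any oracle would run.
- **PERMANOVA**: pseudo-F on Bray–Curtis distances of relative
  abundances, permutation p-value `(1 + #{F_π ≥ F})/(1 + B)`, seeded; an
  exact enumeration mode covers tiny designs. Its null constrains both
  centroid and dispersion, so unequal covariances alone produce
  rejection — a feature the unequal-covariance scenario demonstrates, not
  a defect. Bray–Curtis with 999 permutations is the community default
  for relative-abundance tables (199 inside the simulation harness to
  keep grids desk-scale).

## Synthetic data generator

One simulation cell draws, per replication:

- μ_L¹ with independent Uniform(0, 10) components (redrawn each
  replication; `freeze_mu` fixes it per cell);
- s = ⌊sparsity_fraction · p⌋ signal positions uniformly without
  replacement, redrawn each replication (`freeze_signal` fixes them);
- signal sizes δ_j ~ Uniform(−2√2, 2√2) at those positions, and
  μ_L:j² = μ_L:j¹ − δ_j √σ_L:jj² √(log p / n) with n = n1 + n2, where
  σ_L:jj² is the j-th diagonal entry of the group-2 covariance. The
  ±2√2 endpoints are a package default on the scale conventional for
  sparse-alternative designs, configurable via `signal_low/high`; the
  signal scale shifts power curves but does not affect any calibration
  property.
- L^g ~ N(μ_L^g, Σ_L^g) via Cholesky factors cached per cell; then
  A = exp(L), R = closure(A), X = CLR(R) (exactly the row-centered L).

Covariances are fixed per cell from the cell seed. Base structures have
unit diagonal: banded σ_jk = ρ^|j−k| for |j−k| ≤ bandwidth (defaults
ρ = 0.5, bandwidth = 3) and sparse ± magnitude off-diagonals with
probability `density` (defaults 0.05, 0.3), shifted by (|λ_min| + 0.05)I
and renormalized to unit diagonal when indefinite. Each Σ_L^g is then
given heterogeneous per-component variances, Σ = D^{1/2} Σ* D^{1/2} with
d_j ~ Uniform(0.5, 2.5) drawn independently per covariance matrix
(`heterogeneous_var=False` disables this). Heterogeneous variances are
the standard convention in high-dimensional mean-testing designs, and
they matter scientifically here: with unit diagonals in both groups the
pooled-variance test is per-component correctly scaled even when
correlation structures differ, and the equal-covariance-assumption
failure mode the unequal scenario exists to exhibit would vanish. With
independent variance draws and n1 < n2, components where group 1 is
noisier than group 2 are under-standardized by pooling, inflating the
pooled max-type test (~2–3× the nominal level at the default settings)
while the Welch-type statistic is unaffected.

Scenarios: `"unequal"` = banded (group 1) vs sparse (group 2) with
independent variance draws; `"equal_banded"` / `"equal_sparse"` share
one matrix between groups.

Everything is a pure function of (cell seed, replication index) through
`numpy` `SeedSequence`s, so grids are reproducible and resumable per
cell.

### What the generator does not emulate

Real profiles have zero inflation (the generator's abundances are
strictly positive; zero handling is exercised through the pseudo-count
path on rounded counts), overdispersed sequencing noise on top of the
composition, taxonomic correlation structure beyond
banded/sparse-plus-scale, and uneven sequencing depth (immaterial by
compositional invariance, which is tested). Passing the simulation suite
therefore validates calibration and power behavior under the log-normal
latent model, not robustness to count-level noise at shallow depth.

## Harness problem sizes

The acceptance suite runs the unequal-covariance null at the design's
grid points with 1,000 replications (MECAF at p = 100, n = (100, 200);
MEC at p = 150, n = (100, 300)); PERMANOVA at 200 replications × 199
permutations; the equal-covariance scenarios at 500 replications across
sparsity {0, 0.05, 0.1, 0.2}; the Gumbel-convergence check at 2,000
replications; and the mock-split procedure at 500 splits of one
homogeneous 300-sample, 100-taxon cohort — the same scale as the
simulated cohorts, where the asymptotic calibration is in its working
range. Monte-Carlo standard errors at these sizes are ≈ 0.007–0.022 on
rejection probabilities; the test tolerances (e.g. power monotonicity
slack 0.06 ≈ 2 SE of a difference at 500 replications) follow from them.

## Zero handling and rank aggregation

Zeros are replaced by a pseudo-count before closure; the default 0.5 is
the customary half-count for count tables. The function is
scale-agnostic: for tables already normalized to relative abundances the
caller must supply a pseudo on that scale (e.g. half the smallest
nonzero proportion) — the package deliberately does not guess. No other
zero-replacement model is provided.

Lineage strings are rank-prefixed and semicolon-delimited
(`k__;p__;c__;o__;f__;g__;s__;t__`, MetaPhlAn-style). Aggregation at a
rank sums taxa sharing the lineage prefix up to that rank; taxa lacking
the rank fall into a per-rank `unclassified` bucket so per-sample totals
are conserved exactly. Across-rank reports give raw p-values by default
(each rank is a separate screen of the same global hypothesis);
Bonferroni/Benjamini–Hochberg adjustment is available behind `--adjust`.

## Numerical and degenerate-input conventions

- Component with zero variance estimate and zero mean difference
  contributes 0 to the maximum; zero variance with nonzero difference is
  an error (the statistic is undefined, not infinite — typically a
  duplicated-constant column).
- Composition rows must sum to 1 within 1e−10·p, CLR rows to 0 within
  1e−8·p; natural logs throughout.
- Group labels enter the statistic symmetrically; which label is "group
  1" only relabels n1/n2 (tested). The lexicographically smaller label is
  group 1 unless ordered explicitly.
- PERMANOVA permutation counts below 99 are refused (p-value resolution);
  tie comparisons use a 1e−12 slack on F.

## Known limitations

- The Gumbel calibration is an asymptotic device: for p < 10 it is
  refused-with-warning territory, and mid-range p-values are mildly
  conservative at moderate p (see above).
- The pooled-test inflation magnitude under the unequal scenario depends
  directly on the variance-heterogeneity range (`var_low`, `var_high`);
  the defaults produce clear (2–3×) but not extreme inflation.
- No covariate adjustment, paired designs, or repeated measures; the
  test is a global screen, not a per-taxon discovery procedure.
- Aggregation is lineage-prefix based; no phylogenetic-tree-aware
  grouping.
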