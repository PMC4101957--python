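# Methods

## The testing framework

`permgsa` tests the self-contained null for each gene set: no gene in the
set is associated with the phenotype. Under this null the sample labels
are exchangeable, so every set-level P-value is a subject-permutation
P-value — the fraction of label permutations whose statistic is at least as
extreme as the observed one. The fraction is taken over exactly `nbPerm`
uniform random permutations with no +1 correction, so a set whose observed
statistic beats every permuted draw reports P = 0; callers who need
strictly positive P-values can switch to the (1 + #)/(1 + nbPerm)
convention (`plus_one=True`, `--plus-one`). Permutations are drawn with
replacement from the permutation group (the identity is not excluded and
uniqueness is not enforced); at nbPerm ≥ 1000 the effect is negligible,
and the convention keeps the estimator an unbiased Monte-Carlo average.
Because P(p ≤ α) for an exact permutation P at finite nbPerm is the
discrete quantity ⌊α·nbPerm + 1⌋/(nbPerm + 1), empirical rejection rates
carry an inherent +O(1/nbPerm) term above α; the null-calibration tests
account for it.

One permutation index matrix, keyed by the seed, is shared across all sets
and all statistics of a run. This makes the across-set FWER adjustment
coherent (min-P needs a joint null), reproduces results bit-for-bit under
a fixed seed, and guarantees that appending a set to the collection leaves
the other sets' P-values unchanged.

Competitive (gene-sampling) nulls are deliberately out of scope: gene
sampling produces dependent null draws and answers a different question.

## Set-level statistics

**Standardization.** For categorical phenotypes each gene is standardized
as y\* = (y − ȳ)/s with ȳ the grand mean over all N samples and s the
pooled within-group SD (denominator N − c). Genes with zero pooled
within-group variance would divide by zero, so validation drops them with
a warning before testing (and drops any set thereby reduced below 2
genes); cleaning is idempotent.

**OLS (c = 2).** T_ols = 1'd / √(1'V1) with d = z₁ − z₂ the per-gene
differences of standardized group means, and V = S_pooled·(1/n₁ + 1/n₂)
where S_pooled is the pooled within-group covariance of the standardized
values on the set's genes. This choice of V makes 1'V1 the sampling
variance of 1'd under normality, which is what gives the statistic its
approximate t(N−2) behaviour; the permutation null is used regardless.
The test is one-sided — the caller picks the upper tail (group 1 higher)
or lower tail — and the statistic's sign reports direction. Group order is
order of first appearance in the sample row.

**Hotelling T² / Wilks' Λ (c ≥ 2).** H is the between-group SSP matrix and
E = (N − c)·S\* where S\* is the shrinkage estimate (below) of the pooled
within-group covariance, computed from the within-group residuals. Λ is
evaluated through the generalized symmetric-definite eigenproblem
Hv = λEv, taking the min(m, c − 1) largest eigenvalues, which equals
det(E)/det(E + H). Small Λ is extreme (lower tail). For c = 2 the package
reports T² = (n₁n₂/N) d'S\*⁻¹d, and (N−2)(1−Λ)/Λ = T² holds exactly
because both use the same S\* — the test suite asserts this identity at
1e-10 relative tolerance.

Shrinkage is applied *unconditionally*, not only when m > N: a single code
path keeps observed and permuted statistics strictly comparable and avoids
a discontinuity at the singularity threshold.

**Shrinkage estimator.** The sample correlation matrix is shrunk linearly
toward the identity, leaving variances untouched:
r\*_ij = r_ij·min{1, max(0, 1 − λ̂\*)},
λ̂\* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r²_ij, with the empirical variance
estimator Var̂(r_ij) = n/df³ Σ_k (w_kij − w̄_ij)² on standardized products
w_kij = x̃_ki x̃_kj. When the statistics pool over g groups, the input is
the matrix of within-group residuals and all denominators use df = n − g
(g = 1 for plain observations recovers the usual n − 1 form). If every
off-diagonal correlation is exactly zero the intensity is +∞ and the
estimate is the diagonal matrix of sample variances. For λ̂\* ∈ (0, 1) the
shrunk correlation matrix is positive definite, hence invertible; the
off-diagonal entries never exceed the unshrunk ones in magnitude, and the
estimate is scale-equivariant.

**Per-gene detail.** For sets significant at α the result table attaches
per-gene two-sample pooled-t statistics (c = 2) or one-way ANOVA F
(c > 2) with parametric two-sided (t) / upper-tail (F) P-values and the
gene's rank among all genes. These feed only the report and the GST-plot
shading (default shading threshold 0.01), not the set-level decisions,
which is why parametric P-values suffice there.

## Post hoc comparisons (c > 2)

When the MANOVA is significant, pairwise Hotelling T² tests localize the
difference. Three pair-selection schemes: Dunnett (each group vs the
reference — the first group in order of appearance), Tukey (all
c(c−1)/2 pairs), sequential (each vs the previous). Each pair's raw P
permutes labels only within that pair's samples (the pairwise null
concerns those two groups alone), and the family is adjusted single-step
by max-T across the scheme's pairs. Each pair's permutation stream is
keyed by the pair itself, so a pair's null draws are identical in
whichever family it appears — enlarging the family can then only increase
an adjusted P. Parametric Dunnett/Tukey critical values are not
implemented; everything in the package is permutation-based, and the
multivariate analogues of those critical values would not be.

## Across-set multiplicity

**BH-FDR.** Step-up adjusted values adj_(r) = min_{j≥r} p_(j)·m_total/j,
capped at 1. The family size `m_total` may exceed the number of supplied
P-values for the situation where only the k smallest P-values of a large
family are in hand; the supplied values must then be the family's k
smallest (the suffix minimum runs over the supplied ranks).

**Permutation FWER.** Single-step Westfall–Young min-P: each permutation's
statistics are converted to per-set raw P-values against their own null
column, the row minimum forms the null distribution of the smallest P, and
each set's adjusted P is the fraction of row minima at or below its raw P.
min-P operates on ranks, so it is invariant under monotone transformations
of the statistic scale and mixes statistics of different scales safely; a
max-T variant is exposed for users who prefer comparing statistics
directly. Single-step (not step-down) adjustment is deliberate: adjusted
values are then not forced to be monotone in the raw-P ordering, each
set's adjustment reflecting its own null column.

## Random-forest scores

The RF test asks a predictive question: can the set's genes predict the
phenotype better than chance? The score is the OOB misclassification rate
(categorical) or OOB MSE (continuous); lower is better, and Eq-style
counting P = #{R⁽ᵏ⁾ ≤ R₀}/N uses ≤ so that ties count as extreme. A fresh
forest is grown for every phenotype permutation — the null distribution of
the score itself is required, and reusing trees would correlate the draws.
Samples never out of bag (possible at very small tree counts) are excluded
from the score with a warning.

Forest settings follow the classic randomForest conventions: 500 trees by
default, mtry = ⌊√m⌋ for classification and max(1, ⌊m/3⌋) for regression,
terminal nodes of at most 5 cases for regression. Classification forests
are scikit-learn `RandomForestClassifier`s; importance is the mean
decrease in Gini impurity. Regression forests are a compact numba-compiled
CART implementation inside the package (`permgsa.forest`): the permutation
test refits tens of thousands of forests on samples of a few dozen rows,
and a compiled tree builder makes such a fit a sub-millisecond operation,
which is what keeps the benchmark harness and the permutation null
affordable; its OOB MSE agrees with scikit-learn's on identical data.
Regression importance is Breiman permutation importance — the mean
increase in OOB MSE when a feature's values are permuted among each tree's
OOB samples — reported on the MSE scale. (Describing this quantity as a
"decrease in MSE" under permutation is a common slip: permuting an
informative variable *increases* the error; the package names it
accordingly.) Stratified k-fold cross-validated error is available for
categorical phenotypes, with classes dealt round-robin into folds so k may
exceed the smallest class; k = N gives leave-one-out.

## Synthetic benchmark

The generator reproduces the evaluation design the package is benchmarked
under. Per replicate: gene means ~ U(0, 10), variances ~ U(1, 5), rows of
the n × p expression matrix i.i.d. multivariate normal with correlation

    ρ_ij = ρ           1 ≤ i ≠ j ≤ p1          (compound symmetry)
    ρ_ij = ρ^|i−j|     p1+1 ≤ i ≠ j ≤ 2p1      (AR(1))
    ρ_ij = 0           otherwise,

and phenotype Y = Xμ + ε (linear) or exp(Xμ) + ε (nonlinear), ε ~ N(0, I).
Null: μ = 0. Alternative: five positions among genes 1–20 drawn from
N(ν, |ν|) and five among genes 21–40 from N(−ν, |ν|), the rest zero. Two
genuinely open choices were fixed as follows: |ν| is a *standard
deviation*, not a variance (the SD reading keeps the ν → 0 limit
degenerate at zero and is the usual notation in this literature), and the
expression matrix, effect positions and effect values are *redrawn every
replicate* (matching the plain reading of "replicated" and averaging over
design randomness rather than conditioning on one X).

`rejection_rate` runs any test callable `(X, Y, seed) → p` over n_reps
seed-derived replicates and reports the fraction with p ≤ α — type I error
under ν = 0, power otherwise. Full-scale settings are 1000 replicates ×
1000 permutations × 500 trees; the package's routine checks and the
acceptance script use a reduced 200 × 200 × 100 scale, whose binomial SE at
a true rate of 0.05 is about 0.015 — the scale chosen so the whole
benchmark grid runs in minutes on one CPU while Monte-Carlo noise stays
well below the effects being checked. At ρ = 0 and n = 20 the RF
regression test has modest power even at large ν (a forest of
depth-limited trees approximates a 10-gene linear signal poorly at that
sample size — scikit-learn's forest scores identically), so the
power-monotonicity check in the suite runs at ρ = 0.5 where the trend
clears Monte-Carlo noise comfortably.

What the generator does *not* emulate: heavy-tailed or skewed intensity
distributions, gene-gene correlation outside the set's two blocks,
batch/technical covariates, and measured-array artifacts (missingness is
rejected at input). Passing the calibration suite therefore shows the
tests are exact under exchangeability and well-behaved under the stated
correlation structures — not that real arrays satisfy those structures.

## Numerical and degenerate-input policy

- Zero-variance genes are dropped with a warning at validation (they make
  standardization and correlation undefined); sets reduced below 2 genes
  are dropped — a set must be multivariate.
- `1'V1 ≤ 0` in the OLS statistic and non-finite eigenvalues in Λ raise
  errors rather than returning NaN.
- Shrinkage requires n ≥ 3 and at least 2 residual degrees of freedom.
- Wilks eigenvalues are clipped at 0 before forming Π 1/(1 + λ) to absorb
  −1e−16-scale round-off from the generalized eigensolver.
- Phenotype auto-detection treats a first row of ≤ 10 distinct
  integer-like labels, each appearing at least twice, as categorical;
  anything else is continuous. Explicit kinds override.
- GMT matching is case-sensitive and exact — silent case-folding hides
  identifier errors.
- Categorical groups need n_i ≥ 2; continuous phenotypes need ≥ 3 distinct
  values.

## Reproducibility

Every entry point takes one integer seed. Substreams are spawned via
`numpy.random.SeedSequence` keyed by structural position (set index,
replicate index, pair identity), so results are bit-for-bit reproducible
and insensitive to how many other sets/replicates run alongside. The
compiled forest uses a single deterministic RNG stream per fit.

## Known limitations

- OLS is restricted to two conditions; for c > 2 the MANOVA carries the
  burden (the one-sided global statistic has no canonical c-group form).
- Set-level parametric P-values are intentionally absent — permutation
  only — so very small P-values are resolution-limited by nbPerm.
- The FWER column is single-step; step-down variants would be tighter but
  are not what the adjustment here models.
- The RF regression test is conservative and can be underpowered at small
  n with purely linear, uncorrelated signal; it shines for nonlinear
  association and correlated sets.
- No probe-to-gene collapsing, normalization, or imputation: inputs are
  assumed preprocessed, and missing cells are an error.
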