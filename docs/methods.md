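# Methods

## Problem and model

Given expression matrices X⁽¹⁾ (N₁ × P) and X⁽²⁾ (N₂ × P) for the same P
genes in two phenotype groups, a module is called differentially
co-expressed when its within-module similarity structure differs between
groups: H₀ : S⁽¹⁾ = S⁽²⁾ against H_A : S⁽¹⁾ ≠ S⁽²⁾, where S⁽g⁾ is a P × P
similarity matrix.  Two similarity measures are implemented:

* **Spearman correlation** (default): rank correlation with average ranks
  for ties; robust to monotone transformations of expression.
* **Signed TOM**: from the signed adjacency a_ij = |(1 + corr_ij)/2|^β with
  β = 1, the topological overlap
  TOM_ij = (a_ij + Σ_{u≠i,j} a_iu a_uj) / (min(k_i, k_j) + 1 − a_ij),
  k_i = Σ_{u≠i} a_iu, which rewards shared neighbourhoods.  β is kept at 1
  so that correlation-vs-TOM comparisons isolate the effect of
  neighbourhood averaging rather than soft-thresholding.

Most statistics act on the paired strict lower triangles V⁽¹⁾, V⁽²⁾
(length λ = P(P−1)/2, fixed column-major order; every statistic is
permutation-invariant over entries so only consistency of the ordering
matters).  With d = V⁽¹⁾ − V⁽²⁾:

| statistic | definition | null anchor |
|---|---|---|
| PND(p) | (mean \|d\|^p)^{1/p} | 0 |
| DI | mean d² (≡ PND(2)²) | 0 |
| MAD | mean \|d\| (≡ PND(1)) | 0 |
| pairedT | mean(d)·√λ / √(mean d²) | 0 |
| wilcoxSRT | signed-rank W⁺ of d | λ′(λ′+1)/4 |
| QAP | mean(V⁽¹⁾·V⁽²⁾) | similarity score |
| GCOR | Σ centered(V⁽¹⁾)·centered(V⁽²⁾) | similarity score |
| GHD | mean (centered d)² | 0 |
| GSNCA | Σᵢ \|w⁽¹⁾ᵢ − w⁽²⁾ᵢ\| | 0 |

Notes on deliberate conventions:

* The pairedT denominator is the *uncentered* root-mean-square of the
  differences, not the textbook centered standard error.  Validity is
  inherited from permutation calibration, which does not require a
  t-distributed statistic.  All-zero differences give statistic 0 (its null
  anchor), hence a permutation p-value of 1, instead of 0/0.
* GCOR is an unnormalized centered cross-product (no 1/λ, no variance
  scaling).  Because the permutation p-value is two-sided in |θ|, the
  missing scale constants do not affect inference.
* GSNCA weights are the normalized absolute-similarity row sums
  wᵢ = Σ_{j≠i}|S_ij| / Σ_k Σ_{j≠k}|S_kj|, the "proportional to the sum of
  correlations" description, rather than the original eigenvector-based
  weight vector of the GSNCA method; the two coincide in spirit (highly
  connected genes get large weights) but not numerically.
* wilcoxSRT drops zero differences and uses average ranks for ties
  (the base-R `wilcox.test` convention).  Differences are rounded to 10
  decimal places before zero-removal and ranking: rank correlations are
  rationals, and exact ties/zeros would otherwise be destroyed by
  floating-point noise that differs between equivalent computation orders.

## Permutation calibration

No statistic here has a tractable null distribution, because triangle
entries of a correlation matrix are mutually dependent.  P-values come from
group-label permutation: pool the N₁+N₂ samples, reshuffle labels
preserving group sizes, recompute both similarity matrices *from scratch*,
recompute θ, and report

p = [Σ_b I(|θ(b)| ≥ |θ|) + 1] / (B + 1).

The formula is applied verbatim to every statistic (|·| is a no-op for the
nonnegative ones); ties count toward the numerator; p ≥ 1/(B+1) by
construction.  No one-sided variant is offered — for the similarity-type
QAP/GCOR statistics (where *small* values indicate difference) the
two-sided rule costs power, which is consistent with their low true
positive rates.

B defaults to 3000 for simulations and 10⁴ for data analyses.  One master
seed plus a per-module stream derived from (seed, CRC32(module id)) makes
module-level results independent of iteration order and bit-reproducible.

The engine vectorizes shuffles in chunks of 512.  Within-group ranks are
obtained by double argsort, which equals average ranking exactly when the
pooled data are tie-free within every gene column (always true for the
continuous simulations); if any column contains ties the engine switches to
true mid-ranks per shuffle.  Nothing is cached across groupings — each
shuffle's similarity is computed from its own within-group ranks, as the
permutation scheme requires.  The test suite asserts the vectorized path
agrees with the scalar reference path to 1e-9 on every statistic under both
similarity measures.  A shuffle that makes a gene constant within a group
(possible only with tied data) is either an error or, with
`on_degenerate="redraw"`, resampled and counted.

Multiple testing across modules uses Benjamini–Hochberg FDR (via
statsmodels), adjusted within each statistic across modules — pooling
across statistics would mix differently-scaled null distributions.

## Simulation framework

Expression is multivariate normal with zero mean and unit variances;
correlation structures:

* **CS(ρ)** — constant off-diagonal ρ (ρ ∈ {0.3, 0.7} for null grids);
* **AR1(ρ)** — ρ^|i−j|, heterogeneous decaying correlation;
* **hub** — gene 1 correlates ρ = 0.7 with all others, non-hub pairs share
  a 0.4 background.

Null simulations give both groups the same matrix; the default grids use
N = 25 samples per group and P ∈ {10, 50, 100} (hub: N ∈ {50, 100}).
Alternatives perturb a uniformly chosen proportion γ ∈ {0.1, 0.4, 0.7} of
group 2's lower triangle: dropped to zero, half scaled ×1.5 and half ×0.5
(for CS ρ = 0.5: 0.75 and 0.25), negated (ρ = 0.5 → −0.5), or — for the
sparse-change scenario — a proportion γ of the *hub row* dropped to zero.
The changed-entry count is ⌊γ·positions + 0.5⌋ with a minimum of 1; with an
odd count in the up/down scenario the extra entry goes to the increase arm.
The perturbation pattern is redrawn each replicate, so estimated rates
average over patterns as well as sampling noise.

**Positive definiteness.**  A perturbed matrix can lose positive
definiteness; it is repaired by clipping eigenvalues at 1e-8 times the
largest, reconstructing, and rescaling to unit diagonal (iterated in the
rare case the rescale reintroduces a non-positive eigenvalue; idempotent
and a strict no-op on PD inputs).  The diagonal rescale is a deliberate
choice: eigenvalue clipping alone returns a matrix that is no longer a
correlation matrix.  Notably, the *nominal hub matrix itself* is not
positive definite at the standard parameters (λ_min ≈ −0.040 at P = 10,
−0.178 at P = 50), so the hub builder routes through the same repair; the
sampling target differs from the nominal entries by under 0.02 at P = 10
(e.g. hub correlations 0.683 instead of 0.700).  Under the null both
groups use the identical repaired matrix, so calibration is unaffected.

`estimate_rate` simulates replicate module pairs, calibrates every
requested statistic against one shared set of shuffles per replicate, and
reports the rejection fraction at α = 0.05 (FPR under null scenarios, TPR
otherwise) with its binomial standard error.

What the generator does *not* emulate: real expression is not Gaussian
(counts, heavy tails, batch effects), genes are not exchangeable beyond the
three stylized structures, and modules in real data come from clustering
with its own noise.  Passing rates here show correct calibration and
relative power under the stated models, not performance guarantees on any
particular dataset.

## Problem sizes used in the checked runs

The packaged checks run at reduced scale relative to the full-scale study
profile (1000 replicates × 3000 permutations): the null-calibration tests
use 600 replicates × 1000 permutations per scenario, the all-statistic FPR
grid 600 × 600, the power-ordering checks 150 × 500, and
`scripts/acceptance.py` 500 × 2000.  These sizes keep the binomial
standard error of a rate near 0.01 while remaining cheap; tolerances in the
tests combine the binomial errors of both the reduced run and the
full-scale reference.  The one full-scale-only claim (median TPR > 0.70
across all 51 alternative scenarios for the PND family) is not recomputed;
its reduced-scale surrogate is the power-ordering property
TPR(PND6) ≥ TPR(DI) ≥ TPR(GCOR) under the hub-drop and AR1-drop presets.

## Known limitations

* Only Spearman and signed TOM similarities; no partial correlation or
  mutual information.
* Only multivariate-normal simulation.
* The eigenvalue-clipping PD repair is not numerically identical to other
  repair implementations (e.g. lqmm's `make.positive.definite`, which does
  not rescale the diagonal); per-replicate matrices therefore differ across
  implementations even at equal seeds — only distributional results are
  comparable.
* Asymptotic p-values are deliberately absent; permutation only.
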