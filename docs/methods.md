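# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind the implementation, what the
synthetic-data generator does and does not emulate, and the known
limitations. It is written for a reader who wants to judge what the
package computes and what passing its tests demonstrates.

## Model

For trait *i* (of *t* traits measured on *n* single-cross hybrids) the
mixed model is

    y_i = X_i β_i + Z α_i + Z δ_i + e_i

with `X_i` an intercept column (the only fixed effect), `Z` the identity
(one record per hybrid), `α_i` additive genetic values, `δ_i` dominance
deviations and `e_i` residuals. Stacking traits trait-major (all hybrids
of trait 1, then trait 2, …) the priors are

    α ~ N(0, V_α ⊗ A),   δ ~ N(0, V_δ ⊗ D),   e ~ N(0, R ⊗ I_n)

where `V_α`, `V_δ`, `R` are unstructured t×t trait covariance matrices
and `A`, `D` are the additive and dominance genomic relationship
matrices. Four variants are fit: UV-A and UV-AD analyze each trait
separately (t = 1); MV-A and MV-AD analyze all traits jointly; the A
variants drop the `Z δ` term entirely.

*Kronecker ordering.* `V ⊗ K` (trait covariance first) is the
convention consistent with trait-major stacking; the transposed ordering
`K ⊗ V` describes the same model under individual-major stacking, so the
choice is a pure bookkeeping decision. All code and formulas here use
trait-major stacking.

### Marker coding

Dosages count copies of the A1 allele. With `p` the A1 frequency in the
reference population, the Cockerham codes are

    W_A: 2−2p (A1A1),  1−2p (A1A2),  −2p (A2A2)
    W_D: −2(1−p)²,     2p(1−p),      −2p²

The additive code is linear in the dosage (`W_A = g − 2p`), so fractional
expected-hybrid dosages need no special treatment. The dominance code is
not linear; a fractional dosage is coded as the genotype-class-probability
weighted average of the three codes, with class probabilities taken from
the parental cross (`P(A1A1) = p_λ p_Ω`, etc.) when the parental
frequencies are supplied, and from a symmetric split (`p_λ = p_Ω = g/2`)
otherwise. Both reduce to the exact coding at integer dosages. Hybrids
are coded at the hybrid-population allele frequencies (the reference
population of the relationship matrices is the population being
analyzed); allele polarity is the dosage-counted allele, since polarity
cancels in `A` and only flips effect signs.

### Relationship matrices and spectral repair

    A = W_A W_A′ / (2 Σ_k p_k(1−p_k))
    D = W_D W_D′ / (4 Σ_k (p_k(1−p_k))²)

Monomorphic loci contribute zero to numerator and denominator and may
optionally be dropped. A diallel's `A` is structurally rank-deficient
(its rank is bounded by the number of parent lines, and coding at sample
frequencies puts the ones-vector in the null space), so both matrices are
repaired before inversion: eigenvalues at or below a relative threshold
(1e-8 × the largest diagonal) are replaced by strictly positive values of
decreasing magnitude bounded by a floor of 1e-4 — with r replacements the
least-degenerate direction receives 1e-4 and the most negative 1e-4/r.
Positive eigenvalues are never altered.

### EM-REML

Variance components maximize the residual likelihood via EM. With `C`
the mixed-model coefficient matrix (built with `R⁻¹`-weighted data blocks
and `V_α⁻¹ ⊗ A⁻¹`, `V_δ⁻¹ ⊗ D⁻¹` added to the random-effect blocks) and
`C⁻¹` its inverse, one sweep updates every trait pair (i, j):

    V_α[i,j] ← (α̂_i′ A⁻¹ α̂_j + tr(A⁻¹ C^(ij)_αα)) / n
    V_δ[i,j] ← (δ̂_i′ D⁻¹ δ̂_j + tr(D⁻¹ C^(ij)_δδ)) / n
    R[i,j]   ← (ê_i′ ê_j + tr([W C⁻¹ W′]_ij)) / n_ij

where `n` is the number of genetic-effect levels (hybrids), `n_ij` the
number of records shared by traits i and j, and `W = [X Z Z]`. The
residual trace never needs the dense `W C⁻¹ W′`: each record pair touches
at most nine entries of `C⁻¹`, which the fit gathers directly.

The REML log-likelihood
`−2ℓ = Σ log|R_S| + n log|V_α| + t log|A| (+ dominance terms) + log|C| + y′Py`
is tracked each sweep and is non-decreasing under EM — asserted in the
tests as the primary correctness invariant of the estimator.

*Acceleration.* Plain EM converges geometrically with a rate near 1 for
weakly identified components (hundreds of sweeps at the scales studied
here). The fit therefore applies SQUAREM-style squared extrapolation
every third step: a candidate extrapolated from two consecutive EM steps
is accepted only if it does not decrease the REML criterion (checked with
a cheap Cholesky solve), otherwise the plain EM value is kept. This
preserves the monotone trace and typically shortens trajectories 5–20×.
Convergence is declared when the maximum relative change of all variance
parameters over a plain EM step falls below `tol` (default 1e-6,
`max_iter` 500; the larger experiments in the tests and the acceptance
script use 1e-4–1e-5 and 100–300, which changes estimates well below
their Monte-Carlo noise).

*Degenerate updates.* Updated covariance matrices are projected to the
PSD cone (eigenvalues clipped at 1e-8 × the initial residual scale, which
also keeps a collapsing `V_δ` invertible); a projection triggered by a
genuinely indefinite update sets a flag on the fit. Initial values split
the pairwise-complete phenotypic covariance equally among the fitted
components. A singular variance matrix encountered during assembly
raises an error advising a ridge restart rather than silently
regularizing.

*Missing records.* Records with a missing trait value are dropped from
that trait's data rows while the individual keeps its slot in the random
effect vectors, so its genetic value is still predicted with an
appropriately shrunken BLUP. Residual covariance is handled per
individual on its observed trait subset, so arbitrary missing patterns
are supported; `n_ij` pairs with no shared records keep their previous
value.

## Evaluation statistics

- `r(g, ĝ)`: Pearson correlation of parametric vs estimated genetic
  values, computed for the total (α̂+δ̂ vs g−μ), additive (α̂ vs W_A a*)
  and dominance (δ̂ vs W_D d*) components.
- `h² = cov(ĝ, y)/var(y)` with sample (n−1) denominators; ĝ is α̂ for
  additive models and α̂+δ̂ for dominance models.
- `PRESS = Σ(θ̂−θ)²` for the same three components and for the variance
  components against the realized truth.
- 10-fold CV: whole individuals are masked (all their traits at once —
  the "predict a new hybrid" regime; per-cell masking is available as a
  flag), the model is refit per fold with EM warm-started at the
  full-data variance components, and `β̂ + α̂ + δ̂` predicts the masked
  records. Fold-wise Pearson correlations are summarized by mean and SD
  across folds; a pooled correlation over all held-out predictions is
  also reported and substitutes when folds are too small (e.g.
  leave-one-out). With `refit_variance=False` the full-data variance
  components are held fixed and folds only re-solve the MME; this is used
  where CV ranks model variants (the comparison is symmetric across
  variants) and cuts cost by an order of magnitude.

### Variance-component estimand

A REML variance component `σ²` and the variance realized in a particular
sample are different quantities: for `u ~ N(0, σ²K)` the expected sample
variance of `u` is `σ² · tr(PKP)/(n−1)` with `P` the centering projector.
For a partial diallel this factor is noticeably below 1 (hybrids share
parents), so recovery checks multiply estimates by
`sample_variance_scale(K)` before comparing them with the empirical
variance of the simulated component. The locus-sum formulas

    σ_α² = Σ 2p(1−p)[a + d(q−p)]²,   σ_δ² = Σ (2p(1−p)d)²

are also exposed; they assume Hardy–Weinberg and linkage equilibrium at
the coding frequencies, which a cross between two divergent heterotic
groups deliberately violates (excess heterozygosity), so the empirical
component covariances over the simulated hybrids are used as the ground
truth that the estimator can actually be expected to recover.

## Synthetic-data generator

The generator emulates the construction of maize single-cross hybrids
from a public inbred panel:

1. **Lines.** Fully inbred lines (dosages {0,2}) in two heterotic
   groups; group allele frequencies drift from shared ancestral
   frequencies (uniform on [0.1, 0.9]) under a Balding–Nichols Beta model
   with F = `divergence` (default 0.2, enough for the first principal
   component of `A` to separate the groups, as a real B73- vs
   Mo17-anchored panel does).
2. **Groups.** Recovered by 2-means on the top-2 eigenvector projection
   of `A` — the PCA-based heterotic-group assignment.
3. **Diallel.** Every line of group 1 × every line of group 2; the
   default 20×20 design gives 400 hybrids. The hybrid dosage at a locus
   is the expectation of the parental allelic contributions,
   `E(m) = p_λ + p_Ω` with parental frequency = dosage/2 (exactly {0,1}
   for fully inbred parents; residual-heterozygosity fractions pass
   through unchanged).
4. **Architecture.** Per trait, 100 additive and 100 dominance QTN
   positions drawn without replacement from the marker panel, with a
   fraction (default 0.2) of positions chain-shared with the previous
   trait to induce genetic correlation (shared effect signs aligned so
   the induced correlation is positive); effects are standard normal
   scaled per trait. Trait means default to 0.
5. **Phenotypes.** `g = μ + W_A a* + W_D d*`; residuals are i.i.d.
   normal with `σ_e² = σ_g²(1−h²)/h²`, where `σ_g²` is the empirical
   variance of `g` over the hybrids — this is the reading of the
   residual-scaling expression under which the requested broad-sense
   heritability actually equals `σ_g²/(σ_g²+σ_e²)`, and using the
   empirical variance makes the realized heritability match the request
   up to sampling noise (±0.05 at n = 400). Presets: h² ∈ {0.3, 0.5,
   0.7}, the mixed vector {0.3, 0.5, 0.7, 0.7, 0.3}, and the historical
   five-trait values {PH 0.569, EH 0.662, EL 0.381, ERN 0.57, KW 0.418}.

**What the generator does not emulate:** linkage and recombination (QTN
are in linkage equilibrium given the group frequencies; no genetic map),
marker ascertainment, genotyping error beyond a missing mask, selection
or assortative mating within groups, genotype-by-environment interaction,
and effect-size distributions estimated from real data (effects are
sampled, not derived from a reference panel). Consequently, passing
tests demonstrate that the estimators recover what this idealized
generating process puts in — unbiased variance partitioning, correct
ranking of model variants — not that real maize data would show effects
of the same magnitude.

## Problem sizes used by the tests and the acceptance script

The package defaults reproduce the full design (20×20 diallel, 400
hybrids), and the variance-component recovery experiment (30 replicates,
five traits at historical heritabilities, 100+100 QTN on a 1 000-marker
panel) runs at that full size — dominance variance is noticeably
harder to identify in smaller diallels. The remaining experiments run
desk-scale versions chosen once as informative but cheap: 200 hybrids
(10×20 diallel) for the dominance-direction battery (20 seeds, single
trait, dominance effects scaled ×1.5 so the dominance share of genetic
variance is comparable to the headline traits of the motivating design);
100 hybrids (10×10) with five traits for the four-variant comparison;
120 hybrids with two traits for the multivariate-vs-univariate contrast.
Replicate counts follow the acceptance protocol; sizes are the package's
own choice. Relative bias across replicates is measured per trait as a
ratio of means (mean estimate over mean realized truth): a mean of
per-replicate ratios would be inflated by denominator sampling noise
alone.

## Known limitations

- EM-REML is exact but slow near weak identifiability; fits that stop at
  `max_iter` return `converged=False` with the trajectory attached, and
  the variance estimates may still carry convergence error at loose
  tolerances.
- The MME is solved by dense Cholesky inversion; the intended scale is
  up to a few thousand unknowns (hundreds of hybrids × a handful of
  traits). No sparse or average-information machinery is provided.
- A univariate spec listing several traits is a batch of independent
  analyses; its covariance view is block-diagonal by construction and
  cross-trait entries are reported as 0, not estimated.
- Epistatic kinships, pedigree-based matrices, marker-effect models
  beyond the ridge equivalence check, and unbalanced multi-environment
  designs are out of scope.
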