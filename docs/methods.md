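# Methods

This note documents the models, defaults and numerical choices behind
`commdrivers`, and what the synthetic validation does and does not show.

## Ordination primitives

**RDA.** Responses and predictors are centered internally; the fit is the
orthogonal projection of Y onto span(X) computed through an SVD-derived
orthonormal basis (rank tolerance 1e-10 relative to the largest singular
value). R² = SS(fitted)/SS(total); axes are the principal axes of the
fitted values. Constant or exactly collinear predictor columns either
raise an error naming the column (library default) or are dropped with a
warning (pipeline behaviour); R² depends only on span(X), so dropping
duplicates is exact, not approximate.

**Adjusted R².** Ezekiel's 1 − (1 − R²)(n − 1)/(n − m − 1) with m the
number of independent predictor directions actually used (after cleaning).
Negative values are reported as computed.

**Permutation tests.** Marginal tests permute rows of Y; partial tests
permute residuals under the reduced (conditioning-only) model. p = (1 +
#{F\* ≥ F}) / (n\_perm + 1). Because F is monotone in R² at fixed degrees
of freedom, the marginal test compares R² directly, vectorized over
permutations in chunks.

**Forward selection (double stopping).** The all-candidate model is tested
first; a non-significant global model ends selection immediately
(`global_ns`). Otherwise the candidate with the largest marginal gain is
tested by permutation of current-model residuals; it enters only if p ≤ α
*and* the cumulative adjusted R² stays at or below the global model's.
The rejected-candidate-stops behaviour matches the double-stopping
literature; note that with candidate sets dominated by noise variables the
global adjusted R² can fall below a single strong variable's, in which
case the method legitimately selects nothing — the pipeline then drops
that block and shrinks the 1/K threshold accordingly.

**PLSR.** PLS2 components are computed from the SVD of the
cross-covariance X′Y per dimension with deflation of X only (the NIPALS
fixed point; the test suite checks agreement with an iterative NIPALS
oracle to 1e-8). Predictors are centered and unit-variance scaled
(configurable), responses centered only. Per-component "explained %" is
the share of response variance captured by regressing Y on that score;
because PLS maximizes covariance rather than response variance, the
per-component shares need not decrease with h (the cumulative share is
nondecreasing).

## Multiblock redundancy analysis

Per dimension: v(h) is the dominant eigenvector of Σₖ Y′PₖY with Pₖ the
projector onto the current (deflated) span of block k, computed by SVD
with relative tolerance 1e-10 — rank-deficient and collinear blocks are
handled by the projector without special-casing, which is what lets the
method absorb many collinear predictors. u(h) = Yv(h); block components
are unit-norm *within the block's span* (tₖ = Pₖu/‖Pₖu‖), which makes the
K = 1 case reduce exactly to RDA (verified to 1e-8 in the tests, together
with full-rank saturation: cumulative explained variance equals the
concatenated-predictor RDA R²). aₖ ∝ u·tₖ = ‖Pₖu‖ ≥ 0 and Σaₖ² = 1 by
construction. Y is never deflated; every block is deflated on the global
component t(h), which keeps the t(h) mutually orthogonal and makes the
per-dimension λₕ additive.

Two weight normalizations coexist deliberately: block weights entering the
global component are scaled so tₖ has unit norm (component geometry), while
VarImp uses unit-norm within-block weight vectors so that Σⱼ VarImpⱼ = 1
exactly. Importance indices weight each dimension by λₕ; thresholds are
the agnostic 1/K and 1/P.

**Dimensionality.** Twofold cross-validation with 100 repeated random
splits (pipeline default; 25 in the acceptance script), error = RMSEP
pooled over responses and held-out sites, H\* = smallest h within 1e-6
relative tolerance of the minimum. Folds that cannot support h\_max
(e.g. noiseless low-rank responses exhaust the informative directions)
back off to the largest h they can fit.

**Tolerance intervals.** Site bootstrap (default B = 1000; 199 in the
acceptance script), percentile intervals at 95%. BlockImp/VarImp are
invariant to component sign, so no axis alignment is needed beyond the
per-dimension ordering; replicates that lose predictor rank are dropped
and counted.

## Variation partitioning

Fractions are differences of adjusted R² ([a] = R²adj(A∪B) − R²adj(B),
etc.); the additive identities hold to 1e-10 by construction and negative
fractions are never truncated. Only [a], [b] and the full model are
testable by permutation; the shared fraction [c] is a difference of
adjusted R² values with no permutation distribution and is reported
untested (a negative [c] triggers a warning, flagging suppressor
structure). When one predictor set adds no information beyond the other
(duplicate sets), the pure fractions are exactly zero and their tests are
skipped.

## Co-occurrence null models

**FF algorithm.** The sequential-swap chain picks a random 2×2 submatrix
per attempt and swaps it when it is a checkerboard; failed attempts count
as steps, making the proposal symmetric, so the stationary distribution is
uniform over the margin-preserving class (checked against exhaustive
enumeration of a small matrix by chi-square on the sampled score
distribution). Defaults: 1000 nulls, burn-in 30 000 attempts, thinning
1000 attempts. The pipeline additionally scales burn-in and thinning to at
least 10× and 1× the cell count per matrix (`adaptive_chain`), since a
fixed budget under-mixes large community matrices. Matrices with no
swappable checkerboard are a singleton class: the ensemble is copies, the
test degenerate (p = 1), and a warning is issued.

**CL criterion.** A pair is flagged when its observed C-score falls
outside the null mean ± z·sd confidence band (z the two-sided normal
quantile at the requested level). This parametric reading of "confidence
limits from the null distribution" was chosen after measuring the
alternatives on random matrices: inclusive empirical quantiles are wildly
anti-conservative on the heavily discrete per-pair score distributions
(~29% type I at the 95% level), exclusive quantiles far too strict (~1%);
the parametric band lands near the nominal 5%. Pairs with zero null
variance are classified `random` and flagged degenerate, never
significant. Classification: segregated iff flagged with c\_obs above the
null mean, aggregated iff below.

**Mean-Bayes filter.** Pooled null pair scores define 20 equal-width bins
(top bin closed); the expected count per bin is the mean over null
matrices; in each bin with an observed excess, the ⌈excess⌉ most extreme
CL-flagged pairs by |SES| keep their flag. The Bayes-M set is a subset of
the CL set by construction; the published description of the original
screening procedure does not fix the bin count or allocation rule, so
these are package choices pinned by the subset and restrictiveness
properties in the tests.

## Synthetic data

The generator emulates a 68-site vineyard survey: six abiotic blocks
(Man/Top/Soil/Struc/Land200/Land500, widths 5/5/9/5/6/6), each reading its
own latent standard-normal gradient through per-variable loadings (drawn
from U(0.5, 1.2) in the profile) plus N(0, 1) indicator noise — one
gradient per block keeps block-importance recovery identifiable. Species
respond to the share-weighted composite gradient (profile shares:
topography 0.40, the rest 0.08–0.13) through Gaussian niches with breadth
0.4 sd and log-normal abundance noise; cover below 0.5% is recorded
absent, giving realistic occupancy spreads (~10–50 of 68 sites). Plant
cover is continuous on [0, 100] — the original field protocol's ordinal
cover scale is not emulated. Leafhoppers are Poisson counts around
intensity × (coupling · biotic + (1 − coupling) · abiotic): specialists
track the summed abundance of their host genus, generalists a
Dirichlet-weighted plant composite; profile coupling is 0.7, guilds split
50/50, intensities log-normal around 2 individuals. Planted
aggregated/segregated pairs are imposed by overwriting rows after
background generation, so the intended zero-overlap or identical-occupancy
structure is exact for oracle tests.

What passing the synthetic checks shows: the estimators recover planted
block dominance, coupling-induced shared fractions, and planted pair
classes under a model whose assumptions (one composite gradient, Gaussian
niches, Poisson counts, site exchangeability) they share. What it does not
show: behaviour under spatial autocorrelation, ordinal cover scales,
phenological turnover, or observation error correlated across species —
none of which the generator produces.

When the coupling is switched off the leafhopper generator must be run
with its own abiotic axis (no ground-truth object) for the two communities
to be statistically independent; with a shared environment, independence
at zero coupling cannot hold.

## Problem sizes

Pipeline defaults keep the study-scale analysis settings (9 999
permutations for forward selection, 999 for variation partitioning, 1000
nulls, B = 1000 bootstrap). The acceptance script runs the same pipeline
with 999 selection permutations, 25 CV repeats and B = 199 — sizes chosen
for a desk-scale reproduction; all remaining settings, and every generator
condition, are the defaults.

## Known limitations

* The mbRA importance weighting (λ-weighted squared coefficients) is one
  of several defensible cumulations; it satisfies the sum-to-one and
  threshold conventions but other weightings exist.
* The "most widespread and abundant" rule for common plants is
  operationalized as occupancy rank with a total-abundance tie-break; the
  underlying field concept is not fully specified.
* SES values for strongly structured large matrices can be very large:
  with margins fixed, the matrix-level C-score has tiny null variance, so
  SES magnitudes are not comparable across matrix sizes — use the
  permutation p-values for inference.
* Forward selection inherits the conservativeness of the double-stopping
  ceiling with noise-dominated candidate sets (see above).
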