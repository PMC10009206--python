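# Methods

This note documents the models and procedures implemented in `paleotroph`,
the defaults that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Phylogenies and the Brownian-motion covariance

Trees are rooted with branch lengths in Ma. All phylogenetic statistics are
built on the Brownian-motion covariance **C**, whose (i, j) entry is the
root-to-MRCA path length shared by tips i and j and whose diagonal holds
root-to-tip distances. Zero or absent branch lengths are replaced by
10⁻⁸ Ma (logged): **C** must stay positive definite because GLS estimation
and pFDA whitening invert it.

Fossil tips are grafted at an absolute age (Ma before the host tree's
present). Divergences inside a grafted clade are compressed to a
configurable duration, default 0.001 Ma — the convention of treating fossil
species divergences as effectively instantaneous on the tree's timescale —
and each fossil tip terminates at its own age. Clade depth rescaling
multiplies every branch inside a clade by target/current depth, leaving the
stem and the rest of the tree untouched. Rescaling and grafting are
independent operations; either order is possible and the package does not
privilege one, since calibration workflows differ on this point.

Pruning preserves path lengths between retained tips and suppresses
internal degree-2 nodes, but deliberately retains the original root (with a
single child if needed): this keeps root-to-MRCA depths intact, so the
pruned tree's covariance is exactly the corresponding submatrix of the full
tree's — a property the test suite checks on random trees.

## Phylogenetic signal

Blomberg's K for a trait y is

K = [ (y−â)ᵀ(y−â) / (y−â)ᵀC⁻¹(y−â) ] / [ (tr C − N/ΣᵢⱼC⁻¹ᵢⱼ) / (N−1) ],

with â the GLS mean. K = 1 is the Brownian expectation and is exact when
**C** ∝ I. K_mult generalizes it by summing the GLS-centered sums of
squares across traits before taking the ratio, which makes K_mult equal K
for one trait to machine precision. Significance comes from permuting trait
rows across tips; 1,000 permutations by default. All permutation p-values
use (1 + #{perm ≥ obs}) / (1 + n_perm), so p is never 0 and its floor is
1/(n_perm + 1).

## Pairwise group comparison

"Phylogenetic HSD" premultiplies the data and the one-hot group design by
C^(−1/2) (symmetric eigendecomposition root — unlike a Cholesky factor it
is invariant to taxon ordering) and compares groups by the Euclidean
distance between least-squares means. The null distribution permutes
residuals of the reduced model; the reduced model is intercept-only, the
standard residual-randomization default. Singleton groups are dropped with
a warning rather than erroring, since only groups with at least two members
are comparable. No multiple-testing correction is applied beyond the
permutation p-values themselves. With **C** = I the procedure reduces
exactly to a plain permutation comparison on raw data, which the tests
verify against an independently coded oracle. Classical Tukey's HSD
(studentized range) is provided for non-phylogenetic one-way layouts via
scipy.

## Ordination and discriminant analysis

PCA always uses the correlation matrix: variables are z-scored by the
extant sample's means and standard deviations, putting curvature degrees,
ratios and log masses on one scale. FDA is fitted by optimal scoring with a
linear-regression backend — the canonical non-penalized case, equivalent to
classical discriminant analysis — and its axes are rescaled so the pooled
within-class covariance of training coordinates is the identity; class
posteriors are then Gaussian with identity covariance in discriminant
space. Priors default to training class proportions and can be set equal or
arbitrary; this choice moves fossil posteriors and is therefore explicit in
the model object. Ties in the posterior argmax break toward the first class
in sorted label order.

pFDA whitens extant predictor rows by C(λ)^(−1/2), where C(λ) scales
off-diagonal covariance by Pagel's λ, then fits FDA on the whitened data.
C(λ) is standardized by its mean diagonal before the root is taken; the
standardization is a global rescaling of the whitened space (training
posteriors are invariant to it) and makes λ = 0 on an ultrametric tree give
exactly the identity whitener, so pFDA(λ=0) reproduces FDA and pFDA with
**C** = I is bitwise identical to FDA. λ is profiled on a grid (0 to 1,
step 0.01 by default) by the summed per-variable GLS log-likelihood under
BM with covariance C(λ), each variable's rate σ² profiled out — the
standard Pagel's-λ profile criterion.

Fossils are never part of any fit. They are projected with extant-fitted
means, scales and axes, so adding or removing fossil rows cannot change an
ordination. In pFDA, a fossil has no covariance row in **C**; fossils are
projected on their raw values (identity whitening, self-variance not
modeled). This is an approximation: it treats the fossil as an independent
draw on the standardized covariance scale, which is exact at λ = 0 and
increasingly approximate as λ → 1.

## Body mass

The six-predictor regression returns log₁₀ mass in grams from log₁₀
skeletal measurements in mm (units inherited from the source regression;
the intercept check is unit-free). Masses are always compared on the log₁₀
scale; thresholds are reported back-transformed to grams. The Youden
cut-point scans midpoints of adjacent distinct pooled values plus sentinels
outside the data range — an exhaustive search over all achievable
(sensitivity, specificity) pairs — and breaks ties toward the smaller
threshold for determinism. The diet lumpings behind the two mass contrasts
are invertivores vs {piscivores, scavengers, tetrapod hunters}, and
{folivores, frugivores} vs {granivores, nectarivores}. A fossil's mass
interval straddling a threshold is reported as inconclusive for that
contrast.

## Claw geometry

A claw's outer arc is operationalized as the circle through three
landmarks (base, mid, tip); curvature is the central angle of the
base-to-tip arc passing through the midpoint, in degrees, and arc length is
rθ. The landmark computation centers coordinates on the landmark centroid
first, which keeps shallow arcs far from the coordinate origin
well-conditioned; arcs whose circumradius exceeds 10⁶ × the chord are
treated as straight lines (curvature 0, length = chord). The three-point
scheme is a minimal, exactly invertible stand-in for published landmark
protocols; precomputed curvature/length columns are also accepted, which
bypasses the geometry entirely. Records missing any digit are flagged
incomplete and excluded from ordination rather than imputed.

## Jaw indices

All indices are dimensionless ratios of linear measurements, so absolute
scale never enters. Missing fields yield a missing index without blocking
the others. The ACH denominator is a schema field (cranium length), so a
different length convention is a data choice, not a code change. The
quadrate sensitivity analysis recomputes in- and out-levers as Euclidean
distances from alternative articulation points — typically the extreme
anterior and posterior ends of the articular surface — with the baseline
scenario always reported first.

## FEA intervals

MWAM strain is the area-weighted mean of element strains. Interval
compositions bin percent model area into N equal-width intervals spanning
the pooled [min, max] strain of all models (shared bins are required for
comparability); the top bin is closed, or open above when strains may
exceed the specified range. Zeros are replaced multiplicatively with
δ = 0.65 × the row's smallest positive part, non-zero parts rescaled to
keep the row at 100 and their ratios intact. This is a deliberate
simplification of EM-based expected-value lognormal replacement, which
requires fitted lognormal parameters per column that are not identifiable
from small model sets; the δ fraction is configurable. For highly
concentrated rows where the nominal δ would exceed the row total, δ is
capped so the replaced mass is at most half the row (logged).

clr is log(x / geometric mean); ilr uses a fixed Helmert-type orthonormal
basis with parts in bin order (row k contrasts the geometric mean of the
first k parts against part k+1), so coordinates are bit-reproducible and
ilr is an isometry of the Aitchison geometry, verified against scikit-bio.

Convergence testing raises N stepwise and declares convergence when the
Pearson correlation between consecutive Ns' ordination pairwise-distance
matrices reaches a threshold (default 0.99); degenerate zero-variance
distance matrices count as converged. This distance-correlation rule is a
documented operationalization — convergence criteria for the intervals
method are not standardized — and non-convergence raises rather than
returning silently. Convergence requires reasonably dense meshes: with few
elements per model the sparse upper strain bins flip between zero and
imputed values as N grows and the ordination never stabilizes, so the test
fixtures use thousands of elements per synthetic mesh.

## Diet assignment and synthesis

Diet cut-offs on EltonTraits-style percentages: folivore/frugivore/
invertivore/nectarivore at ≥ 60% of their column, granivore at ≥ 70%
seed, piscivore/scavenger at ≥ 50%, tetrapod hunter at ≥ 60% of
Diet-Ect + Diet-End combined, generalist when no category exceeds 40%.
When two rules fire simultaneously (only possible at the 50% boundaries)
the larger percentage wins and an exact tie is "unclassified", as are rows
matching no rule. Agreement between predicted and true diets is scored with
Fleiss' kappa as named, computed via statsmodels; for exactly two raters
Cohen's kappa is the more conventional statistic, and the Fleiss form is
kept deliberately for comparability. The multi-proxy synthesis thresholds
each proxy's posteriors (default 0.10, configurable), intersects the
"likely" sets category-aware (a diet absent from a proxy's category set
cannot be vetoed by it), and reports likely / unlikely / agreed sets. The
threshold operationalizes what is otherwise an editorial judgment; it makes
the synthesis transparent, not authoritative.

## Synthetic data

The generators produce: random ultrametric coalescent-style trees rescaled
to a chosen depth; multivariate-normal tip traits with covariance
σ²·C(λ_true); labeled shared-covariance Gaussian classes (the regime in
which discriminant analysis is well-specified); diet-stratified masses
normal on the log₁₀-gram scale; log-normal element areas with strains
rescaled so the realized MWAM hits its target exactly (sharp oracles for
MWAM and binning); exactly invertible claw arcs from (curvature, radius);
and EltonTraits-style rows in multiples of 10. Every generator is
deterministic under a fixed seed.

What they do not emulate: measurement error structure of museum specimens,
taphonomic missingness patterns, real FE solver meshes (element counts,
adjacency, stress concentrations), or realistic trait correlations between
proxies. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under its stated assumptions, not that the proxies
discriminate diet in any particular real assemblage.

## Problem sizes and calibration checks

The packaged checks use 32-tip trees with 500 Brownian replicates for the
K calibration, 100 replicates for λ recovery at λ ∈ {0, 1}, 200 null
replicates at 1,000 permutations each for type-I error of K_mult and
phylogenetic HSD (accepted band 2–8% at α = 0.05), ~500 points for the
FDA/LDA agreement oracle, and 60 extant + 3 fossil taxa for the end-to-end
pipeline run. These sizes give stable Monte-Carlo estimates while keeping
the default test run fast on one core.

## Known limitations

- The pFDA fossil projection ignores fossil-to-extant covariance (above).
- The EM-based lognormal zero replacement is simplified to multiplicative
  replacement.
- The claw geometry is a three-landmark reduction of richer published
  landmark schemes.
- Tukey's HSD assumes balanced-ish normal groups; the permutation-based
  phylogenetic HSD is the primary comparison tool.
- The intervals-method convergence rule is one reasonable formalization
  among several.
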