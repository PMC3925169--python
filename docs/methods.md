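# Methods

## Problem

Choice tests offer an organism two food items at once and read preference
from differential consumption — which only works if the two items are
interchangeable apart from the treatment. Wood is a poor substrate in this
respect: veneer discs cut from different sheets (different trees,
provenances, growth histories) differ in density, hygroscopicity and
early/latewood ratio, and even discs from one sheet vary. `veneermatch`
quantifies disc similarity from three cheap physical measurements, groups
similar discs by fuzzy clustering, validates the grouping against the known
sheet of origin, and emits matched pairs for experiments.

## Measured properties

Each disc contributes a 3-vector:

1. **Dry weight** (g), after oven drying.
2. **Moisture absorption** (% of dry weight) after reconditioning at fixed
   humidity: `(wet − dry) / dry × 100`. Negative values (wet below dry)
   are flagged as evaporative loss but returned, so the caller decides.
3. **Mode skewness** of reflected light: the first Pearson skewness
   coefficient `(mean − mode) / sd` of the disc's 8-bit pixel-intensity
   histogram after discarding background pixels below intensity 60.
   Earlywood is pale and latewood dark, so a pale-dominated disc has its
   modal intensity above the mean and a *negative* statistic.

Image conventions are fixed and recorded in output metadata: 16-bit input
is rescaled by 255/65535; colour collapses with Rec. 601 luminance weights;
the mode is taken on the integer histogram (bin width 1) with ties broken
toward the lowest intensity; the standard deviation is the population
(divide-by-n) form. The cutoff (default 60) is a parameter because it is
specific to a lighting setup. The statistic is invariant to intensity
shifts and positive rescalings and changes by < 0.05 under 2× downsampling
of a synthetic disc, which is why modest photo resolutions suffice.

## Feature space and standardization

Features are assembled in a fixed column order (dry weight, moisture %,
mode skewness). Because the three properties live on incommensurate scales
and the clustering distance is unweighted Euclidean, standardization
(z-scoring to population sd 1) defaults **on**; raw mode is retained.
Weights are read at the four significant figures a laboratory balance
reports but never rounded internally.

## Fuzzy c-means

The partition minimises

    J(U, V) = Σ_i Σ_j u_ij^m ‖x_i − v_j‖²,   Σ_j u_ij = 1,  m > 1,

by alternating optimisation: centroids as u^m-weighted means, then
memberships from inverse squared distances with exponent 1/(m−1). A point
coinciding with a centroid receives membership 1 there (split equally over
coincident centroids). Defaults: c = 6 clusters, fuzzifier m = 2,
|ΔJ| < 1e-6 or 200 iterations — well beyond the ~15 iterations typical on
data of this size. Initialisation is a seeded random membership matrix with
normalised rows; the seed is a logged parameter and fits are deterministic
given it. No automatic selection of c is attempted.

Each cluster's members (by maximal membership, ties on specimen id) are
ordered by descending membership and split at 0.5 into a **unique region**
and a **fuzzy region** of discs that could belong to more than one cluster.
By default the fuzzy region keeps the membership ordering so the whole list
is monotone; an alternative mode re-orders fuzzy members by distance to the
assigned centroid (nearest first), for users who prefer a geometric
sub-ordering of the ambiguous tail. The choice is flagged in the output.

## Sorting quality: the neighbor curve

For each cluster list, position p fires at width i when at least one of
the next i entries shares p's source sheet; the curve value at width i is
100 × (firing positions) / (cluster length), swept over i = 1…10. The
window is **one-sided** (successors only) and truncated at the list end;
truncated positions stay in the denominator. One-sided is the default
because under uniform random labels over S sheets the width-1 value then
converges to exactly 100/S — 10% for 10 sheets, 4.5% for 22 — matching the
analytic single-draw null; a two-sided window would instead give
1 − (1 − 1/S)². A two-sided mode exists and is flagged in metadata. Curves
are computed over the full list (unique + fuzzy regions) by default, with
a unique-only option.

Curves are non-decreasing in width and bounded by 100 × (fraction of
members whose sheet occurs at least twice in the cluster); for a
block-sorted list the one-sided window additionally loses the last member
of each sheet block, which caps the plateau at
100 × (L − #sheets present)/L.

Group comparisons reduce each curve to the median of its probabilities,
check normality of pooled centred residuals with the Lilliefors test
(statsmodels), then run a one-way ANOVA (scipy) or, if normality is
rejected, a Kruskal–Wallis rank test. Classical test internals are
deliberately not reimplemented.

## Null models

* **Hypergeometric** (analytic or Monte-Carlo, default 8000 draws): a
  focal disc of sheet s with K_s copies in an urn of L discs has
  probability `1 − C(L−K_s, i)/C(L−1, i)` of a same-sheet disc among i
  draws without replacement; the curve averages over focal discs with
  weights K_s/L. The Monte-Carlo mode simulates a random ordering per draw
  so one draw yields all widths coherently. For *benchmarking* a cluster,
  the urn composition is a near-equal split of the full sheet pool over
  the cluster length (largest-remainder rounding), i.e. the null of
  "random draws from the whole population at this cluster size" — which is
  what makes the hypergeometric curve track the uniform bootstrap.
* **Uniform bootstrap** (default 8 repeats): labels drawn uniformly from
  the sheet pool at the experimental cluster lengths, curves averaged.
* **Balanced bootstrap** (default 10 repeats): every cluster reduced to a
  common target length — the minimum cluster length minus five — by
  resampling its own label sequence *with replacement*; isolates sorting
  quality from cluster-length effects. Requires the minimum cluster to
  exceed five members.

The two repeat counts differ deliberately: each design has its own
conventional repeat count, and both are parameters.

## Pairing

Within each cluster (optionally unique region only), specimens are paired
greedily: the globally closest unpaired pair is taken repeatedly, ties
broken lexicographically, until the next distance exceeds `max_distance`.
Distances are Euclidean in the (standardized) feature space, so a
threshold of e.g. 0.5 means "within half a pooled standard deviation of
each other, jointly over three properties". Greedy matching rather than
optimal matching is a deliberate choice: it is transparent, deterministic,
order-invariant, and near-optimal inside clusters that are already
homogeneous; an exhaustive minimum-total-distance mode exists for clusters
of up to 12. No specimen appears in two pairs.

## Synthetic data

The generator draws per-sheet latent means from
N(global_means, between_sd²) and per-disc properties from
N(sheet_mean, within_sd²), resampling (not clipping) non-positive weights
and negative moistures. Defaults: 10 sheets × 50 discs; global means
(1.3 g, 15 %, −0.5) — a 60 mm × 1 mm pine disc of density ≈ 0.45 g/cm³
weighs ≈ 1.3 g, equilibrium moisture uptake at warm/humid conditioning is
≈ 15 %, and pale-dominated discs give a negative mode skewness; within-
sheet sd (0.025 g, 0.5 %, 0.1) and between-sheet sd three times that,
giving sheets that are distinguishable but overlapping. Pipeline-level
validation uses 6 sheets × 40 discs (240 specimens), a size at which 20
replicates of the full analysis run in seconds.

What the generator emulates: the sheet-banded structure of real veneer
property profiles, with Gaussian between- and within-sheet variation. What
it does not: heavy-tailed or skewed property distributions, correlations
between the three properties within a sheet, measurement drift, and
photographic artefacts (illumination gradients, knotholes, fungal
staining). Passing tests therefore demonstrate the statistical machinery
under the hierarchical-Gaussian model, not robustness to those real-data
features. The synthetic disc image is concentric pale/dark banding with
Gaussian pixel noise on a near-black background — enough to exercise
grayscale conversion, background cutoff and the skewness sign, not a
texture model.

## Numerical choices and degenerate inputs

* Membership rows re-normalise exactly each iteration; row sums hold to
  1e-9 (observed: ~1e-16).
* The cost sequence is non-increasing by construction of alternating
  optimisation; tested on every fit.
* All-identical data, singleton clusters, empty foregrounds, zero-variance
  histograms and zero-variance feature columns raise typed errors rather
  than returning NaNs.
* Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage seeds (all < 2³¹) from one master seed via `SeedSequence` and
  records them in the run manifest. Reruns are byte-identical.

## Known limitations

* Fuzzy c-means finds local optima; a bad seed on hard data can converge
  to a poor partition. The seed is logged precisely so this is auditable;
  multi-restart selection is not built in.
* The neighbor statistic depends on list order only through ties in
  membership, broken by specimen id; clusters with many exactly-tied
  memberships (rare with continuous data) would make the curve sensitive
  to id naming.
* The distance threshold for pairing is a proxy for "probability of
  equivalence"; calibrating it against consumption data is outside the
  package's scope.
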