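# Methods

## Model

sdmshift estimates a presence-background maximum-entropy (MaxEnt) model: the
probability distribution over landscape cells with maximum entropy subject
to (soft) constraints that its feature expectations match the presence
sample's feature means. Equivalently, it is the Gibbs density
q(x) = exp(λ·f(x))/Z fitted by minimizing the convex objective

    J(λ) = −(1/m) Σ_presences λ·f(x_i) + log Z(λ) + Σ_j β_j |λ_j|

over a background sample of cells (uniform, without replacement; presence
cells are appended to the background for the normalizer, the usual
target-background union). The L1 weights β_j = β_mult · s_j/√m shrink noisy
features harder when presences are few; s_j is the feature's standard
deviation over presences, floored at 0.001 of the feature's training range
so that near-constant features are still penalized. This single rule is a
deliberate simplification of the MaxEnt software's per-feature-class
interpolation tables, which are not part of the published record of the
method this package re-implements; the β multiplier (default 1.0) is the
single regularization knob.

Assumptions worth stating: occurrence records are treated as an unbiased
(after thinning) sample of where the species is, background cells as a
sample of available environment, and the landscape as static within a
period. Nothing in the model corrects for survey effort or detection.

### Features

Continuous variables are min-max scaled to [0,1] with bounds frozen from
the training sample; projection data outside the bounds are **clamped**,
not extrapolated. Feature classes: linear, quadratic, pairwise products,
forward and reverse hinges at `n_hinge_knots` (default 20) evenly spaced
interior knots of the scaled range, and one indicator per categorical level
seen in training. Hinges on a fixed knot grid (rather than one knot per
data value) keep the basis bounded and deterministic. Threshold (step)
features are omitted: dense hinges subsume them. Constant variables are
dropped with a warning.

### Optimization

Cyclic coordinate descent. For each feature: a soft-threshold step on the
local quadratic model (curvature = the feature's variance under the current
q, floored at 1e-12), then halving backtracking on the exact 1-D objective
until it decreases. The running log Z is renormalized against an exact
log-sum-exp once per cycle. Iteration stops after `max_iterations` full
cycles (default 500) or when a full cycle improves the regularized gain by
less than `convergence_tol` (default 1e-5 nats). Coordinate descent was
chosen over batch gradient methods because each accepted update has a
well-defined gain improvement attributable to one feature — this is what
makes percent contribution well defined. On small instances the solution
matches a generic convex optimizer to |Δλ| < 1e-4 (asserted in tests).

Degenerate inputs: an all-shrunk model (large β) is the uniform
distribution, returned without error; non-finite feature values raise.

### Outputs and interpretation

Raw output q sums to 1 over the background. The reported suitability is the
logistic transform p = c·q/(1+c·q), c = e^H with H the entropy of q over
background; under the uniform model p = 0.5 everywhere. Percent contribution
credits each accepted coordinate update's gain to the variable owning the
feature (products split 50/50), floors negative accumulations at zero, and
normalizes to 100. Jackknife importance refits with each variable alone and
with each variable excluded, reporting regularized training gain and test
AUC per reduced model. Response curves sweep one variable over its training
range with the others pinned at background means (categorical at the modal
level); replicate-averaged curves report mean ± SD across replicate models.

## Pipeline conventions

- **Thinning**: greedy scan keeping a point iff ≥ `min_km` (default 2 km,
  inclusive boundary with 1e-9 km roundoff slack) from every kept point.
  With no seed the scan runs in input order; a seed shuffles scan order.
  The result is always maximal (no dropped point could be re-added) though
  not necessarily maximum-cardinality.
- **Collinearity**: Pearson |r| screened at a background sample; pairs with
  |r| strictly above the threshold (default 0.8; equality retained) are
  resolved worst-pair-first, dropping the lower-priority name if a priority
  list is given, else the member with the larger mean |r| against all other
  variables (lexicographic tie-break: the later name is dropped).
  Categorical layers bypass the filter.
- **Splits**: test size is round-half-up of `test_fraction · n` (87 points
  → 22 test / 65 train). Replicate i derives all its randomness from
  `base_seed + i`.
- **AUC**: rank-based Mann–Whitney with ties counted half, background cells
  serving as pseudo-absences.
- **Classification**: thresholds 0.2/0.4/0.6 with boundary semantics
  high ⇔ p ≥ 0.6, moderate ⇔ 0.4 ≤ p < 0.6, poor ⇔ 0.2 ≤ p < 0.4.
  "Suitable" for change maps and centroids means p ≥ 0.2. Classification
  is applied to the replicate-mean map.
- **Areas**: exact spherical cell areas, R = 6371.0088 km. Class shares are
  reported against the suitable (not total) area, rounded to integers;
  change percentages are reported against the current suitable area to two
  decimals. The accounting identities stable + loss = current suitable and
  stable + gain = future suitable hold exactly by construction.
- **Centroid**: area-weighted mean of cell centers with p ≥ 0.2 (optionally
  weighted additionally by p); longitude averaged arithmetically, which is
  fine away from the antimeridian. Shift = haversine distance + initial
  bearing; bearing is NaN for a zero shift.
- **Grids**: ESRI ASCII only, corner-convention headers (center-convention
  inputs converted on read), values north-to-south, half-open cell lookup
  anchored at the lower-left corner. Misaligned stacks are an error — the
  package never resamples; inputs must be pre-aligned upstream.

## Synthetic landscapes

`synthetic_scenarios` states a 200×200-cell world at 30″ resolution
(≈ 1.7° × 1.7°, lower-left 112°E 28°N) with: a temperature layer (°C) on a
north–south gradient (4 °C per degree latitude — deliberately steep so a
full climate band fits a small, fast domain) plus smooth noise; a
precipitation layer (mm) on an east–west gradient; an altitude field
(0–300 m smooth noise); distance to water from a random 1%-density water
mask via a Euclidean distance transform with per-axis ground sampling at
the central latitude (a locally flat approximation, adequate for a <2°
domain); a pure-noise layer and a four-level categorical land-use layer as
negative controls. True suitability is the inverse logit of a band response
centred at 7 °C (the 4–10 °C wintering band) and 150 mm (the 110–190 mm
band), altitude decay (preference below ~100 m) and a strong water-distance
decay, mirroring the dominant role of distance to water for a wetland
waterbird. The weights are set so the truth is strongly structured (Bayes
AUC ≈ 0.97 at the default scale): the recovery criteria are only meaningful
when the stated world is actually learnable. Presences are drawn with
probability ∝ suitability × cell area and placed uniformly within the cell.

The future scenario perturbs only the dynamic layers (default +1.2 °C,
×1.05 precipitation; static layers pass through unchanged as conservative
prognoses) and records the closed-form displacement of the suitability
optimum (Δ/gradient degrees north for additive warming, and the analogous
longitudinal displacement for multiplicative precipitation scaling).

What a green recovery test does establish: the full pipeline, run blind on
occurrences sampled from a known truth, recovers high held-out
discrimination, ranks a truly informative variable first, and detects the
imposed northward displacement. What it does not establish: realism of any
GCM scenario, robustness to sampling bias or detection error (not
modelled), or behaviour on grids much larger than the stated world.

A note on the centroid-magnitude check: the suitable region is the climate
band intersected with near-water cells, so each seed's measured centroid
displacement carries zero-mean sampling wobble from the random water mask
(σ ≈ 6 km against an imposed 33 km displacement). The per-seed bearing is
asserted per run; the displacement magnitude is asserted on the across-seed
mean, which is the unbiased estimate of the imposed displacement.

## Known limitations

- The β rule approximates, not reproduces, the MaxEnt software's default
  regularization; fitted λ will differ from that software in detail.
- Logistic (not cloglog) output; the output type is a config enum.
- No bias grids, cumulative output, MESS maps, or hinge pruning.
- No projections/reprojection: everything is geographic lon/lat, and area
  sums use the sphere, not an ellipsoid or a projected grid.
- Jackknife with a single variable is undefined (raises) since the
  without-variable model would be empty.
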