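# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The occupancy model

Each retained species–point pair ("unit") has latent presence
z ~ Bernoulli(ψ) and per-visit detections y_j | z ~ Bernoulli(z·p_j).
The likelihood marginalizes z:

    L = ψ ∏_j p_j^{y_j} (1−p_j)^{1−y_j} + (1−ψ)·1{Σ_j y_j = 0}.

**Occupancy predictor.** logit ψ is linear in: species-standardized
elevation e\* and e\*² (a species' mapped elevational limits correspond to
e\* = −1 and +1), each interacted with a −1/+1 indicator for species whose
elevational minimum is at sea level (lowland species plausibly truncate
differently at the bottom of their range); a monotonic ordinal effect of
distance-to-range (below); land use coded forest = +1, pasture = −1;
species traits and land-use × trait interactions; and crossed Gaussian
random effects — species, family, species×cluster and species×subregion
intercepts, species elevation slopes, species and family land-use slopes.
Subregions are axis-aligned 20-km grid cells over point coordinates.

**Detection predictor.** logit p carries observer effects (sum-to-zero
coding), standardized time after sunrise, land use, species traits, and
species/family/species×observer intercepts plus species time and
species/family land-use slopes.

**Monotonic distance-to-range effect.** Distance-to-range (negative inside
the range) is discretized into 8 equal-width ordinal bins over
[−160, 160] km. The contribution at bin k is b·Σ_{l≤k} ζ_l with ζ a
7-simplex, so the effect runs monotonically from 0 to b across bins; ζ is
parameterized as the softmax of unconstrained values with standard-normal
priors (a uniform-like, exchangeable prior on the simplex).

**Biogeographic clipping.** A species–point pair enters the model only if
distance-to-range < 160 km, e\* ∈ (−3, 3), and the species is in season.
Distance-to-range is computed only against range within the point's
topographic unit: range isolated behind a major topographic barrier does
not count, and a species with no range in the unit is clipped outright.

**Priors.** All coefficients have zero-centred Gaussian priors; random
effect SDs have half-Normal priors. Default scales are N(0, 1) for
intercepts and N(0, 0.5) for slopes and RE SDs, with two per-term
overrides: the land-use coefficient N(0, 1) and the species land-use slope
SD half-N(0, 0.75). The overrides reflect that the forest–pasture contrast
is the focal quantity and is routinely of multi-logit magnitude in
tropical birds, so its prior must stay weakly informative, while the many
remaining slope terms (the quadratic elevation column alone reaches 9 at
the clipping boundary) must jointly keep the prior-predictive occupancy
distribution away from 0 and 1. Under these defaults the prior pushforward
places ≥ 90% of its mass at occupancy probabilities in [0.01, 0.99], which
is asserted by a test. All scales are overridable per term via
`ModelSpec.prior_sd_overrides`.

**Fitting.** Random effects use the non-centred parameterization
(effect = σ·z, z ~ N(0,1); σ optimized as log σ with the Jacobian term),
which keeps the joint posterior mode well defined. The mode is found by
L-BFGS-B with analytic gradients of the marginalized likelihood (the
gradient is verified against finite differences in the tests). Posterior
draws come from a Laplace (Gaussian) approximation at the mode, with the
Hessian obtained by central finite differences of the analytic gradient
and regularized to positive definite by escalating jitter if needed. A
`method="map"` mode skips draws, and `method="emcee"` runs an
affine-invariant ensemble sampler initialized at the mode for small
parameter counts; split R-hat and bulk ESS are computed for every
parameter via ArviZ, and parameters with R-hat ≥ 1.02 are flagged, not
failed. The Laplace approximation is exact only for a Gaussian posterior;
its interval calibration at the reference synthetic scale is checked
empirically by the recovery test (90% intervals for the land-use
coefficient covered the generating value in 20/20 seeded replicates).

**Pixel prediction.** For hypothetical all-forest and all-pasture 2-km
pixels, each posterior draw combines the fixed effects and fitted
species/family effects with a subregion effect freshly sampled from its
fitted distribution (prediction pixels lie in unsampled subregions) and
sixteen independent cluster effects — one per 500-m sub-cell of the pixel,
the grain of a sampling cluster — averaged on the probability scale.
Clipped species–pixel pairs get occupancy exactly 0.

## Cross-scale metrics

Sensitivity of species s over a pixel set P is
S = Σ_{i∈P} ψ_forest,i / Σ_{i∈P} ψ_pasture,i; species whose pasture total
is below 10⁻⁹ are treated as infinitely sensitive and excluded from
community distributions with a logged count. The species pool of a scope
at threshold τ (default 0.2; 0.1 and 0.3 as alternates) is every species
reaching occupancy τ on at least one of the scope's pixels in either
scenario. Community response is the 0.25/0.5/0.75 quantile of S over the
pool (linear interpolation between order statistics — the conventional
default; the choice matters only at small pool sizes), reported also as
percent decline 100·(1 − 1/Q).

For the multi-region analysis, S is computed study-wide and the region
only selects species through its pool; for the hexagon analysis S is
recomputed within each cell. Region-pooling trajectories draw random
region sequences, grow the pool as the union of the pooled regions' pools,
and report the metric relative to the all-region metric, averaged over
sequences and summarized over posterior draws with a mean and 90%
interval. At k = R the union is the full pool by construction and the
relative value is set to exactly 1. The "percent more severe" summary is
100·(metric_all / metric_k − 1) averaged over sequences and draws.

## Hexagon scaling

Grids of regular hexagons at nominal areas {290, 860, 2,600, 7,800,
23,000, 70,000} km² (six log-spaced scales; smaller ladders are used on
synthetic landscapes in proportion to their extent) are randomly offset
within one lattice cell and rotated within the 60° symmetry group, one
fresh grid per posterior draw by default. Cells overlapping the study
rectangle by < 60% are dropped; pixels belong to the cell containing their
centre. Multiplicative beta-diversity is γ (cell-pool richness) over mean
pixel α; the invariant β ≥ 1 holds because γ bounds every α. Excess
regional loss is log(regional percent decline / mean local percent
decline); cell–draw pairs with a non-positive loss at either level are
excluded and counted. The per-draw line of best fit is closed-form OLS —
the grid covers the whole domain, so within-draw standard errors are
deliberately not computed — and uncertainty bands are pointwise quantiles
of the fitted lines across draws.

## Generalized dissimilarity models

Sørensen (b+c)/(2a+b+c) and Simpson min(b,c)/(a+min(b,c)) dissimilarities
(pairs with an empty community get d = 1 and are flagged) are regressed on
predictors through d̂ = 1 − exp(−η), η = α₀ + Σ_j f_j, where each f_j is a
non-negative combination of three order-2 (piecewise-quadratic) I-spline
bases with knots at the predictor's minimum, median and maximum — the
convention of the reference GDM implementations. Site-level predictors
(elevation, precipitation) contribute |f_j(x_i) − f_j(x_j)|; pair-level
predictors (geographic distance, valley and mountain barriers) contribute
f_j(d_ij). Fitting minimizes (weighted) squared error under
non-negativity bounds via L-BFGS-B with analytic gradients; observed
dissimilarities of exactly 1 make the unpenalized optimum unbounded along
monotone directions, so coefficient magnitudes at saturation are
determined by the optimizer's stopping rule — partial-distance *curve
shapes* and comparisons between strata are the meaningful outputs.

The Bayesian bootstrap draws flat-Dirichlet site weights per replicate
(default 400), maps them to pairs by product-and-renormalize (the natural
bilinear extension; the mapping from site to pair resampling weights is a
modelling choice), and refits. The detection-corrected variant samples
each unit's latent state from its conditional — certain presence given any
detection, else Bernoulli(ψΠ(1−p_j)/(ψΠ(1−p_j)+1−ψ)) — once per posterior
draw and fits a single bootstrap replicate per draw, so occupancy and
sampling uncertainty propagate together. Observed communities pool
detections across a point's visits (one community per point).

On synthetic landscapes, the mountain-range label of a site is its
topographic unit and the divide side is the west/east half of the extent;
the mountain-barrier ceiling is a configurable, dataset-specific constant
(default 4,100 m, a typical highest sampled elevation in high-Andean
surveys, above most passes of the main cordillera).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
a planar-km geometry (no projections): a regular 2-km pixel grid whose
elevation is a sum of Gaussian ridges rescaled to a configured range;
biogeographic regions as contiguous vertical strips and topographic units
as horizontal bands, so the two partitions cut across one another; a
smooth tilted-plane precipitation surface. Species ranges grow by
randomized breadth-first search on the pixel lattice (contiguous by
construction), with a configurable endemic fraction confined to one region
— the dial that sets between-region beta-diversity. Elevational niches are
anchored to elevations available inside the range so species are not
trivially clipped out of their own ranges. Traits are a configurable named
set (binary coded −1/+1, continuous standardized); the default five —
forest dependency, invertebrate diet, log mass, elevational breadth, range
restriction — stand in for the kinds of traits used in field studies,
not any specific published list. Sampling places paired forest/pasture
clusters (< 21 km apart, < 200 m elevation difference when attainable) of
three points ≥ 200 m apart, with four visits per point (2–3 configurable)
by one of a configurable number of observers.

Default generative parameters are chosen as a realistic tropical-bird
community: mean land-use effect 0.75 logits (forest-favouring on average)
with species SD 1.0, so the community contains both winners and losers;
hump-shaped elevational occupancy; a 2-logit occupancy decline across the
distance-to-range bins; spatial random-effect SDs of 0.75 (high
small-scale heterogeneity); baseline per-visit detection ≈ 0.3 declining
through the morning. The generator draws z and y by independent Bernoulli
given the linear predictors — it does not emulate abundance, sound-recording
identification, weather gating, or spatially autocorrelated *residual*
structure beyond the modelled random effects. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
assumed model, not robustness to the misspecifications real field data
carry.

## Problem sizes used in the tests

Unit tests run on a 40×40 km landscape with 30 species and 10 cluster
pairs. The simulation-based recovery check uses the reference scale of
150 species and 80 clusters × 3 points × 4 visits, 20 replicates, fitted
with the reduced model (species/family intercepts, species land-use
slopes) on data generated without spatial random effects. Scaling and
dissimilarity analyses in the tests use constructed occupancy cubes where
the expected answer is computable by hand or brute force; region counts,
sequence counts and bootstrap sizes are scaled to the fixture (the
package defaults remain 1,000 sequences, 100 draws, 400 bootstrap
replicates).

## Known limitations

- The Laplace approximation can miscalibrate intervals for parameters with
  skewed posteriors (random-effect SDs near zero in small data); the
  ensemble-sampler backend is the cross-check for small models.
- Full-Hessian finite differencing scales quadratically in parameter
  count; beyond a few thousand parameters use `method="map"` and draw-free
  summaries, or fit the reduced specification.
- Distance-to-range uses pixel-centre geometry; sub-pixel range edges are
  not resolved.
- GDM coefficients saturate when many observed dissimilarities equal 1
  (see above); deviance-style fit summaries beyond RMS are out of scope.
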