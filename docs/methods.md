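# Methods

`viscperc` reimplements, on fully synthetic data with known ground truth, an
analysis pipeline for the question of how observers judge the viscosity of
liquids across very different scenes: a bank of midlevel shape/motion
feature ratings is reduced by factor analysis to a small number of latent
perceptual factors, a linear regression maps those factors to viscosity
judgements, and the frozen model is tested in scene contexts it never saw.
Around that core sit measurement-based comparison models (optical flow,
silhouette statistics, 3D mesh metrics) and representational analyses
(RDMs, pixel- vs feature-space PCA).

Because no human data ships with the package, every stage runs on data from
the synthetic generators below. All randomness flows from one master seed
through fixed per-component offsets; every pipeline output is reproducible
byte for byte from (config, seed).

## Stimulus designs

Two stimulus sets mirror the standard two-set design:

* **Set 1** — one "pouring" scene, 32 viscosities log-spaced from 0.001 to
  80.30 Pa·s, each cut into 6 time periods → 192 stimuli.
* **Set 2** — 8 scene configurations × 7 viscosities log-spaced from 0.004
  to 7.74 Pa·s, full 10 s sequences → 56 stimuli.

Viscosity grids are geometric progressions between their stated endpoints
(`viscosity_grid`). The canonical perceptual scale is 64 geometric steps
from 0.001 Pa·s (water) to 100 Pa·s (molten glass); because no closed-form
rule places the 32- and 7-step experimental subsets exactly on that grid,
the subsets are generated directly between their own endpoints and
arbitrary subset selection is left to the caller.

## Height-field liquid simulator

The mesh stimuli come from a deliberately simple 2.5-D simulator, not a
Navier–Stokes solver: the claims under test concern the measurement and
statistics stack, and what that stack needs is controllable,
viscosity-monotone shape variation. A height field h(x, y, t) on an n×n
grid (default 48², domain 1 m²) receives poured volume at the pour location
each frame (default 10⁻³ m³/s at 30 fps) and relaxes by lateral diffusion
with coefficient

    D = C / viscosity,  C = 5·10⁻⁴ m²·Pa·s/s.

C sets the viscosity→shape mapping: the runniest liquid (0.001 Pa·s) floods
the domain within seconds, a mid-range liquid (~1 Pa·s) has a ~0.1 m
diffusion length over the 10 s clip, and 100 Pa·s barely spreads beyond its
pour column, so the full scale maps onto visibly distinct shapes. Diffusion
is applied as an exact Gaussian convolution per frame (reflecting
boundaries), which conserves total volume to machine precision; the
volume-conservation oracle in the tests checks integrated height × cell
area against the cumulative source volume at every frame. Obstacle cells
are approximately no-flux: mass diffused onto them is returned to the
nearest free cell, preserving volume exactly. Scene variation comes from
pour location, source rate, obstacle maps (rings with holes, bars), a
"stir" mode that orbits the pour point, and a mass-neutral multiplicative
noise mode. Each frame is triangulated as a regular-grid surface mesh
(+z up, consistent winding).

Known departures from real liquid data: no inertia, surface tension,
splashing, or true 3D topology (the surface is single-valued in z); mesh
connectivity is fixed over time, whereas real liquid meshes change
triangulation per frame. Tests passing on these stimuli therefore validate
the measurement/statistics stack, not fluid realism.

## Silhouette rendering

`render_silhouette` produces an orthographic side view (along +y) at 4:3
resolution (default 800×600, scaled down in the drivers). Pixel intensity
is the liquid's depth extent along the view axis in metres — an X-ray-style
projection — and the liquid mask is intensity > 0. Height-field sequences
use an exact column-counting fast path; arbitrary closed meshes go through
a signed triangle rasteriser (sum of ±y over front/back faces), validated
against the analytic projection of a sphere (area πr² within 2%, centre
thickness 2r).

## Simulated observers

Ratings are generated from a known 4-factor model. The loading matrix Λ
(20 features × 4 factors) has a block structure of 5 features per factor
with a small cyclic cross-loading (0.05 of the 0.8 primary before column
normalisation; columns unit sum-of-squares). Cross-loadings are kept small
because larger values attenuate exactly the between-factor contrasts that
parallel analysis must detect to resolve all four factors when the factors
are correlated through the shared viscosity axis.

Factor scores per stimulus come in two flavours:

* **iid** — standard-normal scores, used for pure recovery simulations;
* **monotone** — factor k is a logistic response σ(s·(v − c_k)) of
  standardized log₁₀ viscosity with staggered centres (±1.5, ±0.5) and
  steepness 12, carrying 90% of the factor's variance, plus 10% iid unique
  variation. The staircase construction keeps every factor monotone in
  viscosity (so PC1 of the ratings aligns with the physical axis) while
  keeping the factors mutually distinguishable (so Horn's parallel analysis
  finds four, not one). A smooth variant (steepness ≈ 2) is available and
  is the configuration under which the viscosity slider is approximately
  affine in log viscosity.

Feature ratings are clip-to-[0,1] of the column-wise [0.1, 0.9]-rescaled
noiseless signal F·Λᵀ plus iid Gaussian slider noise (default sd 0.05) per
repetition; clipping after noise mirrors a bounded on-screen rating bar.
Viscosity ratings are clip(β₀ + F·β + noise) with default
β = (0.5, 0.05, 0.05, 0.05, 0.05). Repetition counts follow the
experimental protocol: 1 repetition for Set 1 features, 2 for Set 2
features, 4 for viscosity ratings; repetitions are averaged before any
model fitting.

## 3D mesh metrics

Per-vertex principal curvatures come from a batched quadric fit: neighbour
offsets within a 2-ring are expressed in the vertex tangent frame and
w = a u² + b uv + c v² + d u + e v is solved by least squares; κ₁ ≥ κ₂ are
eigenvalues of the shape operator with the sign convention that convex
regions (bending away from the outward normal) are positive. Vertices with
fewer than 5 usable neighbours are undefined; boundary vertices are flagged
and excluded from every integral. Area weights are barycentric (one third
of each incident face), which sum exactly to the surface area. The shape
index is S = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)) with umbilics mapped to sign(H)
and flat points to 0.

The four metrics: M1 = area-weighted mean |H|·|S| (the |S| weighting
up-weights domes/cups and ridges/ruts over saddles, emphasising angular
features; pluggable); M2 = area-weighted Σ|n·ẑ|; M3 = z of the volume
centroid (signed tetrahedra via the mesh mass properties; open meshes fall
back to the area-weighted surface centroid and are flagged); M4 = Σ|K|·area
(total absolute curvature; an |H| variant sits behind a flag). All four are
validated against closed forms — sphere (κ=1/r, S=1, M2=2πr², M4=4π),
cylinder (1/r, 0; S=0.5), saddle, torus (M4=8π), cube and cone centroids —
within 5% at icosphere subdivision 4, plus scaling/rigid-motion covariance
properties.

Aggregation: full-sequence mode takes the per-frame mean; time-period mode
takes the median within each of 6 equal slices and divides by the
across-period median within a stimulus family, compensating for mesh growth
over time. Both end with a z-normalization (population sd) across the
stimulus set; per-scene z-normalization is available and is what the
measurement-model comparison uses, since removing between-scene offsets is
what allows one weight set to apply across contexts. Degenerate designs
(< 2 stimuli or zero variance) raise an error. For liquid height-field
meshes the dry floor (vertices at z ≤ 10⁻⁵ m) is cropped before
measurement so the flat substrate does not swamp the curvature integrals.

## 2D models

Frames with fewer than 300 liquid pixels are excluded (strict "fewer
than"; 300 px is 0.06% of an 800×600 frame, and drivers at reduced
resolution scale the threshold to keep that fraction), and one-pixel-wide
structures are removed by a 2×2 morphological opening before measurement.
The 20 silhouette statistics span area, perimeter (Crofton estimator),
circularity, solidity, convexity, moment-based eccentricity/elongation/
orientation, extent, component and hole counts, centroid height, spatial
extents and spread, and contour-curvature statistics on an
arc-length-resampled (2 px) outer contour. Statistics are averaged over
retained frames and min-max normalised across the stimulus set. The
single-predictor variant takes the mean of the normalised statistics after
sign-aligning each one with the training viscosity labels (with an
arbitrary statistic list, per-statistic polarity must be calibrated; the
calibration is logged). Mean flow speed uses coarse-to-fine iterated
Lucas–Kanade (pyramid depth and warp count exposed), averaged over liquid
pixels by default (a full-frame flag exists), and is validated against
known translations within 10%.

## Factor pipeline

Horn's parallel analysis compares correlation-matrix eigenvalues against
the 95th percentile of eigenvalues from n_random same-shape standard-normal
datasets, counting top-down until the first failure. Factor analysis is
maximum likelihood on the correlation matrix (features standardized with
population sd), unrotated by default; varimax is selectable, and all
recovery tests match columns by Tucker congruence after Procrustes
alignment so they are rotation-agnostic. Column signs follow the
majority-non-negative convention. A Heywood case (uniqueness < 0.005)
raises a warning; uniquenesses are floored only at 10⁻⁸ so that an
(almost) perfect low-rank fit is reported as such rather than distorted by
an artificial floor.

Factor scores use Harman's idealized-variable weights W = Λ(ΛᵀΛ)⁻¹ applied
to standardized data; W is a left inverse of Λᵀ, so noiseless factor data
reproduce their generating scores to 10⁻⁸. Viscosity regression is OLS
with intercept (df = (4, 187) at n = 192). Transfer standardizes the new
dataset with its own mean/sd by default — slider settings are scale-free
per experiment — with training-statistics standardization as an option;
scores and β stay frozen, and the fit report regresses observed on
predicted (df = (1, n−2)). The random-predictor baseline draws iid
standard-normal regressors (E[R²] = k/(n−1) under this null) and inverts
that curve to find how many arbitrary predictors would be needed to match
the factor model's training fit.

## Representational analyses

RDMs are pairwise Euclidean distances in the 4-D factor score space;
construction validates symmetry, zero diagonal, non-negativity, and the
triangle inequality. RDM comparison regresses strictly-lower-triangle
entries (diagonal excluded) of one matrix on the other: n(n−1)/2 pairs,
df = (1, pairs − 2); R² is symmetric in the argument order. Note that two
factor models trained on different datasets recover the latent space only
up to a general linear map (each absorbs its own training standardization),
so even noise-free forward/reverse RDMs agree closely (R² ≈ 0.98) rather
than identically.

Pixel-space PCA flattens each video to one vector (e.g. 400×300×300 frames
= 36 million dimensions), centres every dimension across stimuli, and
eigendecomposes the n×n Gram matrix — exact, and equal to direct
covariance PCA to 10⁻⁶ on small fixtures. RGB inputs are halved and
converted to grayscale with BT.601 weights (0.2989, 0.5870, 0.1140).
Feature-space PCA standardizes the repetition-averaged ratings; PC1's sign
is anchored to correlate positively with log₁₀ viscosity. Viscosity
alignment regresses PC1 on log₁₀ viscosity by default (the stimuli are
log-spaced); an ordinal-rank axis is exposed as an alternative since
either reading is defensible.

## Problem sizes in the drivers

The analysis drivers and the acceptance script run the rating-based chain
at full design sizes (192/56) and the mesh/image stack at reduced sizes —
32² simulation grids, 120-frame sequences sampled every 12th frame,
160×120 renders — which the package treats as its standard working
resolution for the synthetic stimuli; the geometry suite shows the metric
estimators are already within 5% of closed forms at comparable mesh
densities. Full-resolution settings (48², 300 frames, 800×600) remain
available through `RunConfig`.

## Known limitations

* The simulator's shape repertoire is far narrower than real liquids';
  in particular it cannot produce overhangs, droplets, or topology changes,
  so M3's volumetric path is exercised by geometric fixtures rather than
  liquid meshes (which use the flagged surface-centroid fallback).
* Simulated observers are linear-Gaussian with bounded sliders; there are
  no observer-specific biases, sequential effects, or non-Gaussian noise.
* Oblique rotations of the factor solution are not implemented (no oblimin
  backend in the supported stack); rotation ∈ {none, varimax}.
* Measurement-model R² values on synthetic ratings quantify the pipeline's
  behaviour under its own generative model, not human perception; only
  their qualitative ordering (3D metrics transfer across scenes better
  than single-predictor 2D models) is meaningful.
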