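# Methods

This note documents the models and procedures implemented in `hyperniche`,
the defaults they ship with, and what the synthetic test bed does and does
not establish about real data.

## Cumulative temporal slicing

Occurrence records are divided into nested subsets: the first covers a long
initial window (default 1891–1950, so the first niche model rests on a
solid record base), and each later subset adds one decade, the final
breakpoint closing at the last observation year (default 2017). Because
subsets are cumulative, later niche models are supersets *in data*; nothing
forces the fitted boundaries themselves to nest, and the package
deliberately does not assert hypervolume nesting — a one-class SVM boundary
can contract locally as data accumulate. Only the min–max envelope boxes
are guaranteed nested.

Cleaning rules are codified (the field often delegates them to opaque
helper packages): exact duplicates on `(lon, lat, year)` after rounding
coordinates to 4 decimals, suspect `(0, 0)` coordinates, out-of-bounds
coordinates, off-land points when a mask is supplied, and records inside an
optional user-supplied exclusion polygon. Every removal is logged with a
reason, and `accepted + rejected = input rows` is maintained through read
and clean. Cleaning is idempotent.

## Envelope mask and PC space

The envelope is the exact column-wise min/max of the climate values at all
cleaned records — 0th/100th percentiles, not trimmed — and a cell survives
masking only if *every* variable lies inside the box, so any niche model
projected inside the mask is enclosed in the envelope by construction.
Nodata propagates across layers: a cell missing in one layer is invalid in
all.

PCA is of the correlation matrix (variables standardized with ddof = 1),
fitted by default on **all valid masked cells** rather than on the record
values alone: the components must define a transformation of the entire
projection space, and fitting on that same domain avoids extrapolating the
rotation. `pca_fit_on = "points"` switches to record-value fitting.
Retention follows the Kaiser rule (eigenvalue > 1, at least one component).
Each eigenvector's sign is fixed so its largest-magnitude loading is
positive, making output reproducible across eigensolvers. The PCA is fitted
once, on the full-data mask, and reused for every time slice; per-slice
refits would change the coordinate system between periods and make
centroid/extent comparisons meaningless.

## One-class SVM hypervolumes

The niche model is the positive region of a one-class SVM (RBF kernel)
fitted on the raw retained PC coordinates. Defaults γ = 0.5 and ν = 0.01
are the conventional settings for this estimator; ν is simultaneously an
upper bound on the fraction of training records excluded by the boundary
and a lower bound on the fraction of support vectors. The PC axes already
carry the data's variance structure, so no internal rescaling is applied by
default; `rescale=True` standardizes axes first (some reference
implementations do), which changes the kernel's effective metric.

Monte-Carlo integration draws uniformly over an axis-aligned box spanning
the training cloud expanded by 10% of each axis range per side — the
boundary of a ν-soft model can bulge slightly past the training extremes,
and clipping it would bias volumes low. Volume = box volume × inlier
fraction with a binomial standard error; the centroid is the mean of the
inlier cloud and per-axis extents are its min/max, so all three share one
reproducible sample (default 100 000 draws, seed stored with the object).

**Numerical choice.** Free support vectors sit exactly on the `f = 0`
decision surface, but only up to the SVM solver's tolerance; at the solver
default (1e-3) a third of the training points can land an epsilon *below*
zero and a strict `f ≥ 0` membership rule badly violates the ν-property.
The solver therefore runs at `tol = 1e-8` and membership is
`f ≥ −1e-6` — the epsilon absorbs boundary noise only (verified: the
fraction of training points outside stays at ≈0, far below 3ν, across
random blob configurations).

## Overlap statistics

Jaccard and Sorensen similarities are estimated from a single uniform
sample over the componentwise union of the two sampling boxes, classified
by both membership functions. Computing `V(A)`, `V(B)`, `V(∩)` and `V(∪)`
from shared counts makes `S = 2J/(1+J)` an algebraic identity (it holds to
1e-12 in floating point) and keeps the union/intersection bounds
consistent. Default 200 000 draws per pair; binomial standard errors are
reported so downstream comparisons can use principled tolerances. Matrices
are reported in the conventional triangular layout, Jaccard above the
diagonal and Sorensen below.

## Geographic projection and area

Cells are classified at their center values — no sub-cell interpolation —
and suitable area sums spherical cell areas
`R²·Δλ·(sin φ_top − sin φ_bottom)` with the authalic radius
R = 6371.0072 km; the error against an ellipsoidal earth is below 0.3%,
negligible next to Monte-Carlo and boundary uncertainty. Raster convention:
row 0 is the northernmost row, coordinates are cell centers, indices are
half-open.

## Evaluation

The minimum convex polygon of each period's records clips the evaluation
space. When the point cloud spans the dateline, longitudes are re-centered
(+360° on negative longitudes) whenever that shrinks the longitudinal span,
so a Pacific-centred range is hulled as one compact region. MCP area is
computed by shoelace in the cylindrical equal-area projection
(x = Rλ, y = R sin φ), which is exact for polygons with straight edges in
that projection; only area *ratios* enter the pseudo-absence scaling, so
edge-curvature differences are immaterial.

Pseudo-absences are drawn uniformly (with replacement) over valid cells
whose center lies inside the MCP; the count scales with MCP area relative
to the reference (final) period — `n = round(5000 × area/area_ref)`, floor
100 — keeping evaluation effort comparable across nested models. Scaling by
record count instead is available via `scale_by = "n_records"`. The
confusion matrix is counted at cell granularity, presences deduplicated per
cell; TSS = sensitivity + specificity − 1 is prevalence-insensitive, which
is the point of using it with arbitrary pseudo-absence counts.

## Expansion detection in density profiles

Per-period Gaussian kernel densities (Silverman bandwidth, 512-point grid
spanning the data range ± 3 bandwidths) describe each variable and each PC.
Expansion is a reproducible boolean rather than a visual judgement, and it
requires **two** conditions against the first period: the 1%/99% quantile
support must move outward by more than 5% of the first period's support
length, and more than 10% of the last period's values must lie beyond the
first period's bound. The second condition exists because an empirical
extreme quantile estimated from ~75 early records lies inside the
population's true bound, so the support of a ~1100-record cumulative sample
creeps outward even under a perfectly static niche; under that null the
mass beyond the early bound follows its order-statistic distribution
(Beta(≈2, ≈74) for a 1% quantile of 75 records), whose 99.9th percentile is
≈0.10 — hence the 10% default. Raw min–max ranges are reported alongside;
only those are asserted monotone under cumulative slicing.

## Synthetic scenarios

The generator emulates the structure of a global bioclimatic analysis
without any external data: 19 layers are linear mixes of 4 latent spatial
fields (low-order polynomial gradients plus smoothed Gaussian noise), so
the correlation PCA has a known effective dimensionality and the Kaiser
rule retains ≈4 components. An irregular 15% of the grid is masked as
ocean. The "true niche" is an ellipsoid in the standardized latent space —
defined on the latents rather than on all 19 standardized layers because
the layer matrix has rank ≈4 and an ellipsoid there would be
ill-conditioned and equivalent up to the mixing map. Its center drifts and
its radii grow per slice in the expanding scenario; the cumulative truth
region is the union of the per-slice ellipsoids, guaranteeing nested truth
masks. Records are drawn uniformly from the slice's current ellipsoid
cells, jittered within the cell, with years uniform in the slice bounds;
the default schedule yields 75 records in the first period and 1106 in
total across 8 periods (1891–2017).

Defaults were chosen for realism of the test bed: the latent noise
amplitude (0.6) makes climate locally patchy the way real interpolated
climatologies are, and the niche radii leave the final occupied region a
modest fraction (roughly a quarter) of the land — an invader that saturated the whole
admissible space would make evaluation degenerate. Under these conditions
the pipeline recovers the ground truth: retained components 2–6, suitable
areas perfectly rank-correlated with truth areas, first-row Jaccard
decaying with temporal distance, mean TSS ≈ 0.7, and no expansion flags on
the static-niche null.

**What the synthetic bed does not show.** Layers are linear in the latents
with stationary noise — real bioclimatic variables have nonlinear
dependencies, topographic discontinuities and shared measurement error.
Sampling is uniform within the niche, with no spatial autocorrelation of
effort, no coastal bias and no dispersal mechanics; real occurrence data
are heavily effort-biased. Passing tests therefore establish correctness of
the algorithms and their statistical behaviour under a known model, not
robustness to observational bias.

## Problem sizes

Default analysis sizes: 100×200 grid (≈17 000 land cells), 8 periods,
100 000 Monte-Carlo draws per hypervolume, 200 000 per overlap pair. The
test suite and the acceptance script run the same pipeline with reduced
draw counts (2 000–50 000) — at those sizes the binomial standard errors
are still an order of magnitude below every asserted tolerance.

## Known limitations

- No raster resampling or reprojection: input layers must be co-registered,
  and mismatches are an error by design.
- GeoTIFF is not read or written; the ASCII grid format carries the same
  grid semantics in plain text.
- Exact numeric parity with other SVM-hypervolume implementations is not
  claimed: internal rescaling, box expansion and integration schemes differ
  between implementations and are only partially documented elsewhere.
- The MCP is a crude accessibility proxy; it ignores barriers and can
  include large unreachable regions, which inflates specificity for species
  with concave ranges.
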