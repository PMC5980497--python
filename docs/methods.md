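# Methods

This note records the statistical procedures `nicheval` implements, the
choices made where the procedures are under-specified in common usage, and
what the bundled synthetic scenarios do and do not demonstrate.

## Grids, occurrences, thinning

All metrics operate on a regular lon/lat grid with square cells. Cell
intervals are half-open `[edge, edge + cell_size)` in both axes (a point on
a cell's lower-left corner belongs to that cell); rows are indexed from the
north, matching raster reading order. Occurrences that fall off the grid or
on nodata cells are flagged and excluded from metrics with a warning rather
than raising — coastal records routinely fall off rasterized land, and a
hard failure would hide how many records a metric actually used. The counts
of flagged records are surfaced in every report because dropped points
change every metric.

Spatial thinning keeps at most one record per thinning-grid cell. The
thinning grid is anchored at (−180, −90) so that 2.5-arcminute cells
coincide with the tiling of the global bioclimatic datasets this kind of
analysis typically uses; within a cell the first record in input order is
kept, which makes thinning deterministic, order-stable and idempotent. Both
choices are conventions — the operation itself only requires *a* fixed grid
and *a* tie-break.

Raster I/O uses the ESRI ASCII grid text format exclusively. Values are
written with 17 significant digits, so finite values survive a round trip
bit-for-bit; the format is diffable and needs no binary geospatial stack.
Reprojection, resampling and non-square cells are out of scope; two rasters
interoperate only if their geometries are exactly equal.

## Environmental space

The predictor layers are standardized to zero mean and unit variance over
the background (every cell valid in all layers) and decomposed by PCA —
i.e. PCA on the correlation matrix, because climatic layers carry
incommensurate units and covariance-matrix PCA would let high-variance
layers dominate. The retained dimensionality d is the smallest leading set
of components whose cumulative explained variance reaches the retention
threshold (default 0.90), never less than one. Loading signs follow a fixed
convention (largest-magnitude entry of each column made positive) so
results are identical across linear-algebra backends. The PCA is fit on the
background, not on occurrences: the ordination describes what environments
are *available*, and occurrences are then projected into it.

## Minimum-volume ellipsoids

The observed niche is the minimum-volume ellipsoid (MVE)
{x : (x−c)ᵀA(x−c) ≤ 1} enclosing the occurrence points in component space.
The fit solves the dual D-optimal design problem by a Wolfe–Atwood ascent —
Khachiyan's barycentric update plus away steps, which converge linearly
rather than O(1/k). Iteration stops when the duality gap falls below the
tolerance (default 1e−7, cap 10,000 iterations); the result is then rescaled
so the farthest point lies exactly on the boundary, guaranteeing containment
of every input point while keeping the volume within a (1 + d·tol) factor of
the optimum. Degenerate (affinely dependent) inputs raise an error
suggesting dimension reduction rather than returning a flat ellipsoid.

Default coverage is 1.0 — the true *enclosing* ellipsoid — because the
observed niche is meant to span everything ever observed. A robust mode
(coverage h < 1) is available for outlier-contaminated records: points are
peeled greedily by Mahalanobis distance under the survivors' mean and
covariance until ⌈h·n⌉ remain, then the enclosing ellipsoid of the
survivors is fit. This is an approximation of the exact h-subset MVE
estimator, adequate for small contamination fractions; it is not used by
default anywhere.

Ellipsoid volume is V_d · det(A)^(−1/2) with V_d the unit-ball volume.
Uniform sampling inside an ellipsoid (used by the Monte-Carlo Jaccard) maps
uniform unit-ball draws through the Cholesky factor of A.

## Geographic-space metrics

**Thresholding.** With sorted calibration predictions v₁ ≤ … ≤ vₙ and
omission tolerance t, the threshold is v⌊t·n⌋₊₁ — the smallest value after
discarding the lowest ⌊t·n⌋ — and a cell is suitable iff its value ≥
threshold. The closed comparison makes t = 0 (minimum training presence)
yield exactly 0% calibration omission, and raising t can never increase the
suitable-cell count.

**Omission rate, area, CBP.** OR is the fraction of usable evaluation
occurrences on unsuitable cells. Suitable-area proportion is plain cell
counting (a latitude-cosine weighting option exists but is off by default:
the target extents are a few degrees, where the distortion is negligible).
The cumulative binomial probability is the one-tailed P(X ≥ k) for
X ~ Binomial(n, p) with p the suitable proportion, computed through the
regularized incomplete beta (scipy's survival function) for tail stability.

**Partial ROC.** The curve (x = fractional predicted area, y =
sensitivity) is swept over descending prediction values — all distinct
values when ≤ 1,000, else 1,000 equal-quantile classes, which bounds cost
and matches class-based reference implementations. Evaluation occurrences
are reduced to unique usable cells. Per bootstrap replicate,
⌈resample_fraction·n⌉ cells are drawn *with replacement*; the curve is cut
at y = 1 − E with a linearly interpolated crossing point, the model partial
AUC is the trapezoid integral of y over the remaining x-range, the null is
the integral of the 1:1 line over the same range, and the ratio of the two
is recorded. The replicate p-value is the fraction of ratios ≤ 1
(conservative: ties count against the model). Two properties worth knowing:
the ratio is a rank statistic (strictly monotone transforms of the
prediction leave every replicate unchanged), and at very small evaluation
samples the sensitivity curve is coarse, which biases the null ratio
upward — at 50 test points and 500 replicates the null mean sits near 1.04;
at 7 points it can reach ~1.2. Interpret ratios from tiny samples
accordingly.

## Information criteria

AIC = 2K − 2 ln L exactly; AICc adds 2K(K+1)/(n−K−1) and is refused when
n ≤ K + 1 rather than returning a negative correction. K is an input for
models whose internals are not re-run here; two counting rules are
provided: 2p for a quadratic no-interaction GLM (intercept excluded from
the count), and round(N·(p + p(p+1)/2 + c)) for classification models,
where non-integer N is accepted because N is an *average* node or
population count across an ensemble. The raster log-likelihood normalizes
the suitability surface to sum to one over valid cells and sums
log-probabilities per occurrence *record* (records sharing a cell each
contribute), making the result invariant to positive rescaling of the
model output — so whether a model's output was "raw" or "logistic" is
irrelevant up to monotone scaling.

## Environmental-space indices

All counting is over unique environmental combinations: component-space
vectors of suitable cells are deduplicated after rounding to 6 decimals in
component units (the spread of the standardized background is a few units,
so 1e−6 is far below any meaningful environmental distinction).

*Index I* partitions the unique suitable environments by MVE membership
into interpolation (inside) and extrapolation (outside) counts. The point
cloud is taken from the full analysis extent by default; a region mask can
restrict it. The observed MVE is fit to **all** available occurrences —
calibration and evaluation populations — so the question asked is "does
the model predict beyond anything ever observed", not "beyond the
calibration data".

*Index II* pairs a fit measure with a severity measure. Jaccard similarity
has two modes. `ellipsoid_volume` (default): the modeled niche is the MVE
of the model's suitable unique environments and J = V∩/(V₁+V₂−V∩), with V∩
estimated by uniform Monte-Carlo sampling inside the smaller ellipsoid
(default 100,000 samples, fixed seed; standard error on J of order 1e−3).
`discrete_cells`: exact set-based J over unique background combinations,
with the observed niche represented by the background points inside the
MVE. The ellipsoid mode matches the geometric picture of two overlapping
niche envelopes; the discrete mode is exact and is also the automatic
fallback when the suitable cloud is too small or degenerate for an MVE
(the report records which mode produced its number). The degree of
extrapolation is the Euclidean distance in raw component units (no
re-standardization) from the observed centroid to the farthest suitable
environment outside the MVE; zero exactly when the extrapolation count is
zero.

## Synthetic scenarios

The generator emulates the study design these metrics target, not any real
landscape. Layers are affine transforms of √ρ·latent + √(1−ρ)·own, where
the latent field is a strong latitudinal gradient plus smoothed Gaussian
noise and each own field adds a weak random gradient; ρ (default 0.6)
controls inter-layer correlation, reaching affine identity at ρ = 1. The
default grid is 60×60 cells of 2.5′. The true niche is an ellipsoid in raw
layer space centred on the mean environment of the three occupied bands,
axes proportional to the local spread times a breadth factor (default 1.0);
suitability is the bell-shaped exp(−m²/2) of the averaged squared
standardized deviation — a unimodal physiological response. Occurrence
populations (defaults 42 north / 7 central / 61 south, matching the scale
of a small-mammal presence dataset after thinning) are drawn without
replacement, suitability-weighted, from band cells with suitability ≥ 0.5,
and placed at cell centres so the sets are born thinned. North and south
calibrate; the central band is held out.

Pseudo-models: `matched` is the truth; `broad` is truth^0.1, a monotone
flattening; `overfit` is the truth masked to a 3-cell neighbourhood of the
calibration cells; `random` is i.i.d. uniform. Because omission-tolerance
thresholds are empirical quantiles of the calibration predictions, any
strictly monotone transform produces the *same* binary map — so the
broad/matched contrast is invisible to quantile thresholding by
construction. Scenario-level comparisons of the pseudo-models therefore
binarize at a fixed absolute cut of 0.5 on the [0, 1] truth scale (recorded
in the scenario manifest). This is deliberate: it reproduces the situation
where a real overbroad model ranks vast areas above its calibration
minimum, which a rank-preserving synthetic transform cannot.

What passing tests on these scenarios shows: the metrics order contrasting
model behaviours correctly (broad dominates overfit in both index-I
coordinates; matched pairs high interpolation with less extrapolation than
broad; random prediction scores ≈ 1 on partial ROC; matched recovers the
held-out population at the minimum training presence). What they do not
show: robustness to sampling bias, spatial autocorrelation of residuals,
dispersal structure, or biotic interactions — none of which the generator
emulates.

## Numerical and scale choices

- MVE: duality-gap tolerance 1e−7, iteration cap 10,000 — comfortable at
  d ≤ 5 and a few thousand points.
- Monte-Carlo Jaccard: 100,000 samples by default; examples and the full
  pipeline use fewer where the numbers are illustrative.
- Partial ROC: 100 replicates at 50% resampling by default; the null
  calibration checks use 500 replicates on a 100×100 raster with 50 test
  points, sizes at which the run completes in well under a second.
- Acceptance/property checks on scenarios use 60×60 grids with 8 layers;
  a full scenario builds in ~0.5 s, keeping 20-seed sweeps cheap.
- Degenerate inputs fail loudly and specifically: constant layers name the
  layer, affinely dependent point clouds suggest dimension reduction,
  constant predictions refuse a threshold sweep, AICc refuses n ≤ K + 1.

## Known limitations

- The robust (coverage < 1) MVE is a greedy approximation, not the exact
  h-subset estimator; with heavy contamination it can keep the wrong subset.
- The MC Jaccard estimates intersection volume from samples of the smaller
  ellipsoid only; for extremely eccentric near-disjoint pairs the estimate
  at default samples can be coarse (the discrete mode is exact).
- Partial ROC's null ratio is biased above 1 at very small evaluation
  samples (see above); comparisons between models evaluated on the *same*
  occurrences are unaffected.
- Proportional area ignores cell-area variation with latitude unless the
  cosine weighting is enabled.
- No reprojection: all inputs must share one lon/lat grid.
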