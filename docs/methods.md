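# Methods

This note documents the models and procedures `lidarval` implements, the
synthetic scenes it validates them on, the parameter choices that
matter, and what the passing tests do and do not establish.

## The validation problem

Spaceborne LiDAR measures terrain elevation and canopy height in two
very different ways: photon-counting altimetry classifies individual
returned photons (noise / ground / canopy / top-of-canopy) along
100 m × 12 m track segments, while full-waveform instruments record the
entire return-energy profile over ~25 m circular footprints spaced 60 m
apart. Validating either against airborne LiDAR requires (a) correcting
footprint geolocation, (b) extracting commensurable reference values
under each product's sampling geometry, (c) unifying both products onto
a common 30 m grid, and (d) stratifying accuracy by slope, because
terrain inclination converts horizontal geolocation error into vertical
error at a rate of tan(slope).

`lidarval` builds this chain over a synthetic-scene generator so every
stage can be checked against known truth.

## Synthetic scenes

A scene is a 1 m DEM plus a 1 m CHM on a shared grid.

* **Terrain** is a planar ramp at the requested mean slope plus
  band-limited Gaussian noise (white noise smoothed at a correlation
  length, rescaled to a target standard deviation). Defaults: mean
  slope 18.8°, roughness 2 m at 30 m scale — moderately rugged
  subtropical mountain terrain. A staircase builder produces adjacent
  uniform-slope panels (2.5°…50°) for slope-stratified experiments.
* **Canopy** is a union of random disk crowns (radius 2–6 m) with
  heights Normal(20 m, 5 m) truncated at zero, added until the covered
  fraction reaches the target (default 0.628). Optionally the local
  height mean is modulated by a smooth stand-scale field
  (`canopy_height_field_amplitude`, default 0 m; correlation length
  300 m). The field is off by default so constant-height scenes are
  exactly constant; mapping experiments enable it because spatial
  interpolation is only meaningful when canopy height has
  landscape-scale structure, as real forests do.
* **Airborne returns**: Poisson(3.9 pts/m²) points; each is a
  vegetation return with probability 0.8·(1 − e^(−0.3·chm))
  (Beer–Lambert-style occlusion, ~20% ground visibility under a 20 m
  canopy) placed uniformly within the canopy column, otherwise a ground
  return with Gaussian vertical noise (default 0.1 m) truncated at ±4σ.
  Intensities are uniform positive values (vegetation dimmer than
  ground); they only matter through the footprint weighting.
* **Photon tracks**: shots every 0.7 m along-track with uniform
  cross-track scatter in the 12 m segment width. Per shot: a ground
  photon with probability e^(−0.3·chm), Poisson canopy photons placed
  uniformly in the canopy column, and Poisson noise photons (rate
  0.05/shot). The highest canopy photon per 1 m bin is relabeled
  top-of-canopy. A deterministic profile (ground every shot at exact
  terrain height, one canopy photon at the exact canopy top, no noise)
  supports identity tests. Horizontal geolocation error (default 2.5 m
  per axis) is a single offset per track — geolocation bias is a
  per-granule quantity — with per-segment and per-photon modes for
  experiments that need many independent draws. Linkage bookkeeping
  (`ph_index_beg`, `classed_pc_indx` per segment, both 1-based) is
  emitted alongside and is checked by a round-trip oracle.
* **Waveform footprints**: true centers on the track every 60 m;
  reported centers displaced by Normal(0, 5 m) per axis. The attached
  waveform is simulated from the point cloud at the *true* center. The
  product's elevation and RH metrics are extracted from the truth
  rasters at the true center with the same buffer rules the reference
  extraction uses, so product-minus-reference error is purely the
  geolocation displacement — the mechanism under study — and a
  zero-noise configuration reproduces the reference exactly. A
  configurable fraction of footprints (default 0.1) is given a failing
  quality field.

All randomness derives from one master seed split into fixed per-stage
streams, so identical configurations are bit-identical regardless of
call order.

What this generator does **not** emulate: radiative transfer,
atmospheric noise, orbit geometry, off-nadir footprint ellipticity,
multi-layer canopies, and the clustering of real photon returns near
crown surfaces (canopy photons here are uniform in the column, which
gives photon-derived RH percentiles a low bias of roughly 10% of canopy
height — qualitatively matching the known underestimation of
photon-counting canopy products, but not calibrated to it). Passing
tests therefore demonstrate the correctness of the *pipeline*, not the
accuracy of any real product.

## Waveform simulation and geolocation correction

The waveform model is the Gaussian superposition given in the README.
Defaults: σ_f = 6.25 m (25 m footprint diameter read as the 1/e²
intensity width), σ_p = 1.0 m (≈ a 15.6 ns FWHM transmit pulse),
0.15 m bins, vertical range auto-extended 5σ_p beyond the contributing
returns, contribution cutoff at 3σ_f. Two evaluation paths exist:
`exact` (the superposition evaluated at every grid height) and `binned`
(weights accumulated into height bins, then convolved with the discrete
pulse kernel — the same quadrature at O(bins) cost, used inside the
grid search; the two agree to within the 0.15 m binning).

Correction evaluates every lattice offset within the closed 12.5 m
search disk (489 candidates at 1 m step), simulating each candidate on
the observed waveform's height grid and correlating. Ties break toward
the smallest Euclidean offset, then lexicographically. Correlation
requires ≥ 3 bins and nonzero variance; zero-variance waveforms raise
rather than silently returning 0.

Recovery performance depends on scene texture: slope localizes the
along-gradient component strongly (the waveform shifts vertically by
tan(slope) per meter), while the cross-contour component is constrained
only by canopy patchiness and terrain roughness. At the default scene
and additive waveform noise of 1% of peak (a high-SNR power-beam-like
condition), offsets drawn in a 10 m disk are recovered within 1.5 m in
~92% of trials; at 2% noise this drops to ~86% and at 5% to ~66%, with
the residual error almost entirely along terrain contours. Smoothing
the waveforms before correlation does not help — the limit is geometric
near-degeneracy of the correlation surface, not noise bandwidth.

## Reference extraction and quality control

Reference values use buffer zones matching each product's geometry:
100 m × 12 m rectangles oriented along the track azimuth (computed from
the first and last segment centroids) and 25 m circles. A raster cell
belongs to a buffer iff its center lies strictly inside (boundary
excluded) — cheap and deterministic; area-weighting was not used.
H_mean is the arithmetic mean of DEM cells; RH_j sorts canopy heights
of vegetated cells (CHM > 2 m, a conventional canopy threshold,
configurable) and indexes at round(0.01·j·n) (half-up, clamped to
[1, n]; the plain product 0.01·j·n is non-integer for most n, and the
same rounding rule is used everywhere RH percentiles appear, grid cells
included). Quality filtering retains a footprint iff quality_flag = 1,
degrade_flag = 0, sensitivity ≥ 0.9 (inclusive), and
rx_assess_flag = 0; missing fields reject with their own tally.

## Gridding and scale unification

Grid cells live on the global 30 m lattice (cell k spans
[30k, 30(k+1)) — half-open, so every photon lands in exactly one cell
and grids from different sources align). A DEM cell needs ≥ 4 ground
photons; a CHM cell needs ground, canopy, and top-of-canopy photons
simultaneously. Negative relative heights (photons below the local
ground mean) are kept, not clamped, and counted as diagnostics. The
30 m reference aggregates the 1 m DEM by mean and the 1 m CHM by the
RH_j rule over vegetated cells, mirroring the product-side definitions.

## Accuracy assessment

R² and RMSE as defined in the README; slope classes are left-closed
intervals [0,5), [5,15), [15,25), [25,35), [35,45), [45,∞) so every
finite slope has exactly one class (the shared endpoints are assigned
upward). Slope comes from a 3×3 Horn gradient; border cells are NaN.
Strata with fewer than two pairs report n only; R² is withheld when the
stratum's reference variance is zero (flat scenes) rather than reported
as an artifact. The pooled RMSE² is, and is tested to be, the
count-weighted mean of stratum RMSE².

The experiment driver validates both products at footprint scale
(buffer extraction at *reported* positions vs product values) and at
30 m (gridded products vs aggregated reference), stratified by slope.
Identity holds end-to-end only on flat, uniformly canopied, zero-noise
scenes, where product and reference supports coincide; on slopes, the
support difference between photon samples and raster means is itself
part of the signal being studied.

## Geostatistical mapping

Empirical semivariograms use the Matheron estimator with default lag
width equal to the mean nearest-neighbor distance and maximum lag half
the domain diagonal. Fits minimize pair-count-weighted squared error
over (nugget, sill, range) with three range initializations; reported
RSS and fit R² are unweighted over nonempty bins. Model selection takes
the lowest RSS among spherical, exponential, and Gaussian. The
exponential model is γ(h) = C₀ + (C−C₀)(1−e^(−h/a)) with a the
correlation length (effective range ≈ 3a). Caveat established by the
simulation study: from a *single* realization of an exponential random
field (400 samples, a = 100 m), the lowest-RSS model is the exponential
in only roughly half to two-thirds of seeds — empirical variograms
fluctuate enough at the realization level that spherical often fits
better; the median fitted range is nevertheless within ~20% of truth.
Model identity should not be over-interpreted from one survey.

Kriging solves the ordinary system with a Lagrange multiplier (simple
kriging with a global mean is available); duplicate sample locations
are averaged first. The covariance keeps the nugget at zero separation
(C(0) = sill), so prediction at a data location returns the datum with
zero variance — the "exact interpolation" convention. SGS migrates the
(sqrt-transformed) conditioning data to grid cells, then visits the
remaining cells along a per-realization random path, drawing each from
the local simple-kriging distribution given the nearest 16 conditioned
nodes; transformed draws are floored at zero before back-transforming
(squaring) so the back-transform stays monotone. Default 50
realizations; ensemble mean and sd are reported. The mapping loop on a
synthetic scene with stand-scale canopy structure (180 footprint RH90
samples over 1.44 km², 20% held out) achieves hold-out R² ≈ 0.66 and
RMSE ≈ 3.2 m with a fitted range of a few hundred meters; this is a
self-consistency demonstration, not a claim about real forests.

## Problem sizes and numerical choices

Experiments are sized to run comfortably on one CPU: unit scenes are
100–300 m squares; the geolocation study uses 50 footprints over a
4 ha scene (≈ 30 s); the slope staircase uses six 240 m × 90 m panels
and three parallel tracks; the variogram study uses 25 seeds × 400
samples on a 1.5 km square (sample spacing ≈ 60 m, like the waveform
product's footprint spacing); SGS maps a 40 × 40 cell grid with 50
realizations. Matrix solves use dense LAPACK (inverse cached per
kriging fit; a 1e-10 diagonal jitter stabilizes SGS neighborhoods).
Degenerate inputs raise informative errors rather than returning
defaults: empty footprints, zero-variance waveforms, negative slopes,
sub-minimum lag bins, and singular kriging systems after deduplication.

## Known limitations

* Photon canopy sampling is uniform in the vertical; real classified
  photons cluster near crown surfaces, so absolute canopy biases here
  are indicative, not calibrated.
* The LAS writer/reader covers LAS 1.2 point format 0 only (the format
  the pipeline itself writes); rasters are exchanged as ESRI ASCII
  grids, and HDF5 layouts are flat groups named after the standard
  product fields rather than full official product trees.
* Variograms are isotropic; no co-kriging or covariates.
* Waveform correction assumes the airborne cloud covers the search disk
  plus a 3σ_f margin; footprints near the data edge are skipped.
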