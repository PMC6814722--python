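# Methods

## The structural condition index

SCI classifies each 30 m cell by three co-registered inputs. The class
boundaries follow the executable form of the classification (the masking
conditionals), which pins down the edge cases the printed class labels
leave open:

| input | classes | boundary convention |
|---|---|---|
| tree cover (%) | <25, 25–75, >75–95, >95 | `cover < 25` is the masked class, so exactly 25 % is forested; 75 belongs to 25–75 and 95 to >75–95 (upper bounds inclusive) |
| canopy height (m) | 0–5, >5–15, >15–20, >20 | `height ≤ 5` is the shortest class; 15 and 20 close their intervals |
| loss-year code | 0; 1–12; 13–17 | 0 = no loss since 2000; the recent epoch starts at code 13 (year 2013) |

Weight 1 is assigned whenever the cell had recent loss, cover below 25 %,
or height at most 5 m. The remaining nine (height ≥ class 2) × (cover ≥
class 2) combinations score 2–10 for mid-epoch loss and 10–18 for no
loss, increasing with height class first and cover class within it. The
full 33-cell layout is asserted verbatim in the test suite. The table is
a plain mapping object that can be exported to CSV, edited, and reloaded,
for users who want different weightings.

The three input layers carry different reference years (cover 2010,
height 2012, loss through 2017); they are treated as a single nominal
epoch and no temporal harmonization is attempted.

## The structural integrity index

FSII = SCI / w with w ∈ {1, 5, 10} classing the 0–50 human-footprint
score at thresholds `< 4` (low) and `≤ 15` (medium, inclusive on both
sides). The published weight grid's row for SCI = 1 prints 0.2 under low
pressure; the defining formula gives 1.0, and this package follows the
formula. The discrepancy is asserted as a known erratum in the tests
rather than silently absorbed.

The human-footprint raster is usually ~1 km; by default it is upsampled
nearest-neighbor onto the 30 m SCI grid, which preserves the SCI's
resolution and simply block-assigns pressure weights. The alternative
reading — integrity at the pressure layer's resolution — is available via
`at_hfp_resolution=True`, which aggregates SCI to the coarse grid by
modal value before dividing. Both resolutions are legitimate; 30 m is the
default because the index is published at 30 m.

FSII is stored as floating point; every attainable value has at most one
decimal (s/1, s/5, s/10 for integer s), so one-decimal quantization is
lossless if byte-efficient export is wanted.

## Foliage height diversity

Vegetation returns are normalized to height above ground using the k
nearest ground returns in the x–y plane (k = 6, fewer if the cloud has
fewer), weighted by inverse squared distance; a vegetation return exactly
above a ground return takes that return's elevation. Ties in neighbor
distance are resolved by the spatial index; the test oracles use
continuous random coordinates where ties have probability zero.

Normalized heights above 70 m are discarded as cloud/sensor noise.
Slightly negative heights (returns below the interpolated ground) are
clamped to 0 rather than dropped so that they still count toward the
density rule — dropping them would bias sparse-canopy cells toward
exclusion. The density threshold (default 10 points/m²) is evaluated on
vegetation returns only, since height normalization — and hence the FHD —
is defined for vegetation returns.

FHD is the Shannon entropy of the per-cell height histogram on half-open
1 m bins [i, i+1), i = 0..69, with the top bin closed (a 70.0 m return
lands in bin 69). The logarithm is natural, the convention of the
Shannon/MacArthur diversity literature; a `log_base` option switches it.
FHD therefore lies in [0, ln 71], is zero exactly when all returns share
one bin, and is invariant to point order, duplication of the whole cloud,
and joint translation of cloud and grid.

## Validation sampling and models

Lidar footprints and the 30 m grid are never perfectly co-registered, so
samples are restricted to places where misalignment cannot change the
answer: connected components (4-connectivity by default; switchable) of
constant SCI, at least 3×3 cells, eroded by 90 m. The erosion metric is
Chebyshev — "within 90 m of the perimeter" removes 3 cells in every
direction including diagonals — and raster edges count as perimeter.
Applying both rules literally means a minimal 3×3 patch contributes no
core cells; small patches simply drop out. Cells whose loss year is
strictly after the lidar acquisition year are masked first. FHD grids in
their native alignment are brought onto the SCI grid by bilinear
resampling before sampling.

The model suite regresses FHD on SCI as a continuous covariate (a
categorical option exists for per-class prediction): ordinary least
squares, a random transect intercept, and patch nested in transect (one
shared patch variance), the latter two via Gaussian linear mixed models.
All fits use maximum likelihood, not REML, and AIC is computed uniformly
as −2·llf + 2k with k counting fixed effects plus all variance parameters
including the residual — so the OLS and mixed-model AICs are on one
scale. R² is reported in the variance-partition sense: marginal =
fixed-effects variance over total, conditional = (fixed + random) over
total; the conditional value is the headline comparator. Non-convergence
raises with diagnostics rather than returning a silent fit.

## The synthetic generator

`generate_landscape` grows patches from seeded cells by randomized
dilation, assigns each patch an SCI class from a configurable probability
vector (uniform by default), then draws cover/height/loss per cell
uniformly from the class's admissible region of the weight table, staying
0.5 units (0.1 m at the short-height cap) clear of class boundaries so
floating-point round-off cannot flip a class. Class 1, a union of three
causes (recent loss, open canopy, short stature), picks one cause at
random; class 10, attainable from two table cells, picks either. By
construction the classifier inverts the generator exactly, which the
tests assert for multiple seeds. The human-footprint surface is uniform
0–50 per 990 m cell (33×33 fine cells), emulating the ~1 km pressure
grid.

`generate_point_cloud` gives each cell a Poisson number of vegetation
returns at its class's density — 12.4 points/m² for class 1 rising by
0.4 per class, so every class clears the 10 points/m² validity rule while
staying within airborne-survey norms — with heights drawn from a
three-stratum Gaussian mixture (ground vegetation, understory, canopy).
The canopy stratum's mean rises from 2 m (class 1) to 28 m (class 14)
and the mixture broadens with class, so the closed-form entropy of the
1 m binned profile — computable exactly via `expected_fhd` and used as
the recovery oracle — is non-decreasing in class. With `saturate=True`
(default) classes 15–18 reuse the class-14 profile, reproducing the
qualitative flattening of FHD at the top of the condition scale; with
`saturate=False` the profile keeps rising to 34 m. Ground returns are
scattered at 0.5 points/m² on a smooth sinusoidal terrain (amplitude 4 m
over ~1 km wavelengths, zero for exactness tests).

`generate_validation_samples` skips the raster stage and emits grouped
records directly: FHD = 0.6 + 0.15·SCI + u_transect + v_patch + ε with
σ_transect = 0.25, σ_patch = 0.12, σ_resid = 0.08. These defaults put
simulated FHD in the 0.75–3.3 range of closed-canopy tropical forest,
give a strong condition signal, and make grouping variance dominate the
residual — the regime in which the nested model should, and in tests
does, win the AIC comparison in ≥95 % of replicates.

What the generator does *not* emulate: georegistration error between
lidar and the 30 m grid (the patch-core machinery is exercised but not
stressed), spatial autocorrelation of residual FHD within patches,
sensor-specific return multiplicity and scan-angle effects, cloud
contamination (the >70 m filter is tested with injected outliers
instead), and realistic covariance between the three input rasters.
Passing tests therefore demonstrate correctness of the algorithms and
the qualitative behavior of the validation design, not performance on
real archives.

## Numerical and design notes

* GeoTIFF I/O is implemented directly over the TIFF tag set
  (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA, with
  layer semantics in the description tag). Single band only; geographic
  (degree-unit) CRSs are rejected with instructions to project first,
  since all distances (90 m buffers, 30 m cells, kNN in meters) assume a
  metric grid. Integer layers round-trip bit-exactly.
* Grid convention: row 0 is north, origin at the northwest corner, cell
  (r, c) covers a half-open box so point-in-cell assignment is
  unambiguous; a point exactly on the grid's north edge belongs to row 0.
* Bilinear resampling interpolates between source cell centers; target
  cells outside the center lattice, or whose four-neighbor support
  touches nodata, become nodata (no extrapolation, no overshoot).
* Nodata defaults: −9999 for continuous layers, 255 for byte-coded ones.
* Model-comparison ties keep input order (stable sort). Degenerate
  designs (a single SCI value, a single transect) raise errors rather
  than returning unstable fits.
* Problem sizes in the test and example runs — landscapes up to 60×60
  cells, point clouds up to ~5 million returns, 50 mixed-model
  replicates of 1800 records — were chosen so the full pipeline runs on
  a laptop-class single core in well under a minute per stage while
  keeping ≥20 cells per SCI class for the recovery curves.

## Known limitations

* No LAS/LAZ binary reader: point clouds are delimited text (x, y, z,
  LAS class code). Real clouds should be converted with standard tooling.
* No on-the-fly CRS reprojection; all layers must arrive in one
  projected CRS.
* The mixed models fit random intercepts only — no random slopes, no
  spatial correlation structure within patches.
* The pressure thresholds (4, 15) and weights (1, 5, 10) are fixed
  defaults from the vertebrate-endangerment literature; they are
  overridable but no alternative calibration is shipped.
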