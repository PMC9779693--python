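# Methods

This note documents the models behind `esvscape`, the choices made where a
published convention did not pin one down, and what the synthetic test
landscapes do and do not establish about real data.

## Raster model and aggregation

A `Grid` is a north-up, square-pixel, single-band raster (float64 in
memory; float32 on disk) with an explicit nodata mask that propagates
through arithmetic: any nodata operand makes the result pixel nodata.
Pixel (r, c) covers the half-open square anchored at the top-left origin;
centroids sit at pixel centres. Supported formats are ESRI ASCII grid and
GeoTIFF (georeferencing via ModelPixelScale/ModelTiepoint tags, nodata via
the GDAL tag). Reprojection is out of scope: all inputs are assumed to
share one projected, metre-based CRS.

Fine rasters are aggregated to the analysis grid (default 2000 m — a grid
scale fine enough to resolve within-municipality contrasts yet coarse
enough that each cell mixes several land-use patches) in integer-factor
blocks. The per-cell statistic (mean, sum, or majority for categorical
data) runs over valid pixels only; cells whose valid fraction falls below
`min_valid_fraction` (default 0.5, a common GIS compromise for partially
marine or edge cells) are dropped. Per-hectare quantities use the plain
mean, which is exact area-weighting for equal-area pixels.

## Valuation

All six services are valued in CNY per hectare per year; every price,
cost and equivalent factor lives in `EconomicParams`/`HabitatParams`, and
the defaults in `esvscape.defaults` are plausible magnitudes for a coastal
north-Chinese prefecture, not measurements. Name collisions among
conventional symbols (C as both reservoir cost and RUSLE cover factor; P
as price, precipitation and practice factor; Q as quality, grain yield and
area share) are resolved by distinct field names.

Unit conventions worth stating explicitly:

- NPP converts gC·m⁻² to t/ha by ×0.01; one tonne of NPP is taken to fix
  1.63 t of carbon and release 1.2 t of oxygen.
- Water: 1 mm of retained water over 1 ha is 10 m³, so the reservoir-cost
  valuation is `WR · 10 · C`.
- Soil: bulk density in g/cm³ is numerically t/m³, so `S/ρ` is a sediment
  volume in m³ and `S/(ρ·d)` the m² of land whose topsoil (thickness `d`)
  the retained mass represents; the second term divides by 10⁴ to convert
  to hectares before multiplying by forestry income per hectare. The
  RUSLE surplus is parsed as retention = potential − actual, i.e.
  `R·K·LS·(1 − C·P)`.
- Habitat threats decay as `exp(−2.99 d/d_max)` (the InVEST convention:
  influence falls to ~5% at the maximum distance), distances are Euclidean
  to the nearest threat pixel, and the half-saturation constant of the
  quality response is half the maximum observed degradation (0.5 fallback
  on threat-free landscapes); shape exponent z defaults to 2.5.
- The equivalent-factor services use 1/7 of the grain output value per
  hectare as one "equivalent". Aesthetics supports both a uniform per-area
  value (the default, matching how a single corrected regional value is
  spread over area) and a class-resolved variant; the two agree in spatial
  mean.

Every valuation is homogeneous of degree one in its prices, so currency
deflation or revaluation is a pure rescaling.

## Indices

HAI coefficients are the 2-decimal averages of the three expert rows
(Lohani checklist, Leopold matrix, Delphi); rounding is half-away-from-
zero so the printed averages (building 0.94, dry farm 0.59, ...) are
reproduced exactly. Classes with no published row get nearest-analogue
defaults (aquaculture ← water 0.12, mudflat ← other land 0.08, moor ←
wetland 0.14), all overridable. LUI grades follow the published five-level
table; moor and wetland sit in grade 1 with mudflat/unused land (the table
layout groups moor there even though its caption text is ambiguous — the
grade map is a parameter). SHDI and patch density are composition and
configuration metrics per analysis cell; patches are 4-connected and
clipped at cell boundaries, making PD deterministic and cell-local.

## Hot/cold spots

Gi* uses binary distance-band weights with the focal cell included. The
default band is 1.5× the analysis cell size; note that capturing the full
queen neighbourhood on a square grid needs d ≥ √2 × spacing (≈2828.4 m at
2 km), so tests that require queen contiguity use 2830 m. Both the raw
ratio `Σ w_ij x_j / Σ x_j` and the standard deviate are reported; the
significance classes (90/95/99%) come from the deviate, whose finite-sample
standardisation makes the ~5% nominal rejection rate exact in expectation
under random permutation of the field. A zero-variance field returns z = 0
everywhere rather than NaN.

## Geo-detector

The q-statistic uses population (divide-by-N) variances globally and
within strata, as the defining formula carries no n−1 correction; with
sample variances q would shift at O(1/N). Singleton strata contribute zero
within-stratum variance. Significance defaults to the noncentral-F test of
the geo-detector literature, with a seeded label-permutation test
(add-one smoothing) as the assumption-free alternative; the two agree to
~0.01 on medium-signal scenarios. Continuous drivers are discretized into
9 natural-breaks classes before detection; 9 is the conventional choice
and is a flag. The natural-breaks solver is the exact Fisher dynamic
program (O(k n²)); boundary-tied values classify into the lower class for
determinism.

## GWR

The kernel is fixed Gaussian, `w = exp(−½ (d/b)²)`, the convention of the
dedicated GWR packages. Covariates and response are standardised
internally for conditioning; coefficients are reported back-transformed,
which leaves sign maps unchanged. The hat diagonal is computed alongside
each local solve, giving tr(S) effective parameters. AICc follows the
Fotheringham–Brunsdon–Charlton form with the maximum-likelihood sigma
(RSS/n) inside the criterion, while the reported "unbiased sigma estimate"
diagnostic is √(RSS/(n − tr(S))); adjusted R² uses effective parameters:
`1 − (1−R²)(n−1)/(n−tr S)`. Bandwidth selection is a deterministic
golden-section search on [2× median nearest-neighbour spacing, 2× domain
diagonal] to 1% relative tolerance; a monotone AICc returns the boundary
with a warning rather than failing. Near-singular local designs (bandwidth
too small for the cell spacing) and collinear covariates raise informative
errors instead of returning degenerate exact fits. In sign summaries an
exactly zero coefficient counts as positive so the two percentages always
sum to 100. The pipeline fits one univariate GWR per key driver by default
(`gwr_separate=True`), matching the factor-by-factor way such coefficient
maps are usually presented; a joint multivariate fit is a flag away.

## Synthetic landscapes

The generator exists so that every stage can be verified against known
truth. A Gaussian random field (white noise convolved with a Gaussian
kernel of σ = range/2, wrap-around boundary, sample-standardised) is
sliced at its empirical quantiles into a land-use mosaic whose realised
class fractions match their targets to one pixel. Driver surfaces mirror
the correlations real driver stacks show qualitatively: NDVI high on
forest/grassland and low on built land, population and GDP decaying with
distance from built-up pixels, elevation smooth with slope as its gradient,
climate fields smooth and nearly independent of land use. Default class
proportions describe a forest-and-farmland coastal mosaic with a 12%
built-up fringe. All outputs are pure functions of (parameters, seed);
sub-streams derive from the one seed by fixed offsets.

Two scenarios carry analytic truth. The geo-detector scenario draws equal
strata with known means and within-stratum sd, whose population q is
`B/(B+σ²)` with B the variance of the stratum means — e.g. means (0, 1)
with sd 1 give q = 0.2. The GWR scenario evaluates user-supplied smooth
coefficient surfaces β_k(u, v) at cell centroids and builds
`y = β₀ + Σ β_k x_k + ε` with i.i.d. standard-normal covariates, so
coefficient-surface recovery can be scored directly (on the default
30×30-cell, noise-0.5 scenario, GWR's β₁-surface RMSE is ~an order of
magnitude below OLS's and the median absolute error ≈ 0.04).

What passing these tests does **not** show: real landscapes have
anisotropic structure, coastlines, measurement error correlated across
drivers, and land-use classes whose geometry is not a thresholded Gaussian
field; the economic defaults are placeholders. Results on real data depend
on supplying real parameter tables and rasters — the synthetic suite
validates the *computations*, not any region's values.

## Problem sizes and determinism

The bundled analysis and the acceptance checks run on a 64×64-pixel
landscape (256 analysis cells), a 10⁴-cell Gi* null field, a 5000-cell
geo-detector scenario and a 900-cell GWR scenario — sizes chosen so the
whole study re-runs in seconds while keeping the statistical checks
well-powered. Pipeline CSVs are written with a fixed float format and all
randomness flows from one integer seed, so reruns are byte-identical; the
run manifest records seed, parameter hash and per-stage timing (timing
excluded from the determinism guarantee).

## Known limitations

No CRS handling or reprojection; no vector I/O (rasterize upstream); the
CASA light-use-efficiency model is not included (APAR and ε are inputs);
no sediment delivery ratio beyond the fixed deposit fraction; no multiple-
testing correction of Gi* categories; adaptive and multiscale GWR kernels
are out of scope.
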