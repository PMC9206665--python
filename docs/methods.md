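# Methods

## Model and assumptions

The package diagnoses the flooded fraction of a coarse (0.25°) grid cell
from the subgrid distribution of the compound topographic index (CTI)
and a grid-mean water-table-depth surrogate Γ. The underlying TOPMODEL
assumptions are the classical ones: the local hydraulic gradient follows
the local slope, and water-table variations are a succession of steady
states with uniform recharge, so the subgrid water table redistributes
linearly in CTI. A pixel floods when its CTI reaches

    CTI* = mean(CTI) + M · Γ ,

with M an integer per-cell transmissivity-decay parameter searched over
1–15. The empirical curve f(Γ) — flooded area fraction versus Γ scanned
over a plausible range — is reduced per cell to the asymmetric sigmoid
Ψ(Γ) = (1 + v·e^{−k(Γ−q)})^{−1/v} so monthly series cost one formula
evaluation per cell-month instead of a pixel recount.

Sign convention: Γ is depth, positive downward; cells flood as Γ → 0
and dry as Γ grows, so empirical curves are non-increasing and fitted k
comes out negative (k is deliberately left unconstrained in sign; only
v > 0 is structural, keeping the exponent −1/v defined).

Γ is approximated by the soil-moisture saturation deficit
θ_SD = z_{l0} − Σ θ_l Δz_l / θ_S (metres), with θ_S uniform over depth.
Layers at or below the first frozen layer (layer-mean soil temperature
< 0 °C) are excluded; a frozen top layer forces θ_SD = 0. The deficit is
used directly as Γ with no further transform. Three rules additionally
force a cell-month's product value to zero: 70 cm soil temperature below
0 °C, more than five soil-freezing days in the month, or a Köppen
hot-desert (BWh) cell. The 70 cm probe is read from the layer containing
that depth (reproducible across heterogeneous layer schemes; a midpoint
interpolation variant is available via `st_method="interp"`). Known
caveat: the 70 cm rule can zero out months in which shallower layers are
unfrozen; the package mirrors the rule rather than correcting it.

## Calibration

For each cell and each M in 1–15, the empirical curve is computed on a
301-point Γ grid (step 0.01 m over [−1, 2] m — fine enough to resolve
the sigmoid's knee at negligible cost), reduced to (v, k, q) by bounded
nonlinear least squares, and the simulated series Ψ(Γ(t)) (masked months
zeroed) is reduced to the calibration statistic — long-term maximum by
default; yearly maxima, mean seasonal cycle, or all months for dynamic
observations — and scored by RMSE against the observed statistic. The
minimising M wins; ties break toward smaller M for determinism.

The fit is ill-conditioned in v, so it is multi-started over
v ∈ {0.5, 1, 2, 5, 10} with q initialised at the half-maximum crossing
and k from the finite-difference slope there; bounds are
v ∈ [10⁻³, 10³], k ∈ [−10⁴, 10⁴], q ∈ [−10, 10]. Flat curves (range
< 10⁻⁶) are degenerate: the cell falls back to a constant function and
is flagged. Curve points are sampled uniformly and unweighted.

Scoring uses the *unconstrained* Ψ; the cap f = min(Ψ, f_max) is applied
only to final products, since capping before scoring would make all M
with max(Ψ) ≥ f_max indistinguishable. f_max is the observed per-cell
long-term-maximum fraction of the calibration dataset — the only choice
consistent with constraining the simulation by observed maximum extent.
A cell with observed f_max = 0 is masked outright. Rice-paddy removal
from observations is subtract-and-clip, max(0, f_obs − f_rice); multiple
observation datasets combine by per-cell maximum of their long-term
maxima (the union map). Calibration compares fractions, not areas, as
area weighting cancels within a cell. Cells are independent; the
calibration loop is order-invariant and can parallelise over cells
(`n_jobs`).

Numerical notes: Ψ is evaluated in log space,
exp(−logaddexp(0, log v − k(Γ−q))/v), which is exact in (0, 1) for any
argument and cannot overflow. Pixel inclusion at the CTI threshold uses
≥; on continuous CTI values the choice has measure-zero effect. Area
removed from a cell as lakes/ice (pixel areas summing below the cell
area) counts as never flooded, i.e. fractions normalise by the full cell
area. Missing (NaN) soil moisture propagates to missing product values,
written as NetCDF fill.

## Synthetic world

The generator emulates the statistical structure of the real inputs so
the pipeline can be exercised and validated end-to-end without
downloads:

- **CTI subgrids** — one shifted-gamma sample per cell (location 2,
  shape 3, scale 1.5 by default): positive and right-skewed like
  observed CTI histograms. Any positive right-skewed law would do for
  testing; the choice implies nothing about real topography. Pixel
  areas are equal within a cell (the real fine grid is near-uniform at
  cell scale) and sum to the spherical cell area.
- **Forcing** — per layer, θ(t) = clip(θ_S(b + a·sin(2π(t−φ)/12)) + ε,
  0, θ_S) with baseline b = 0.75, amplitude a = 0.18, phase 3 months and
  i.i.d. Gaussian noise sd 0.02 (the simplest stationary perturbation);
  θ_S = 0.45 and layer thicknesses 0.1/0.3/0.6/1.0 m (a typical
  reanalysis-style discretisation, 2 m column). These defaults keep the
  θ_SD surrogate roughly within 0.1–0.9 m — well inside the (−1, 2) m
  fitting range — so the per-cell M is identifiable from the forcing.
  Soil temperature follows a seasonal cycle that crosses 0 °C only in
  cells classed as freezing (Dfc, 15% of cells by default); monthly
  freezing-day counts are zero for non-negative top-layer temperature
  and positive otherwise. 5% of cells are hot desert (BWh).
- **Truth observations** — the forward model itself (empirical curve at
  a hidden per-cell M, sigmoid reduction, mask rules, no cap) generates
  monthly "observations" and their per-cell maximum, making calibration
  an exact recovery problem with a known answer.

Default problem size is a 10 × 10-cell grid at 0.25°, 2,500 pixels per
cell and 120 months — sized so that every experiment, including the full
recovery study, completes in well under a minute on one CPU.

What passing tests therefore show: the machinery inverts its own forward
model exactly, respects every bound and mask rule, and measures what it
claims to measure. What they do not show: skill against real satellite
wetland products, real reanalysis bias structure, or real topography —
the synthetic world has no spatial correlation between cells, no trend,
no observation error, and its CTI law is a stand-in.

## Evaluation metrics

Wetland areas are Σ f · A_cell over a region, in Mkm², with spherical
cell areas A = R²·Δλ·(sin φ₂ − sin φ₁), R = 6371 km (sub-0.5% vs an
ellipsoid). Standard regions are the globe and the three zones
60°S–30°N, 30°N–50°N, 50°N–90°N. Seasonal cycles are calendar-month
means; interannual variability is summarised by per-year statistics —
both annual maxima and annual means are provided, as both conventions
are in use — their sample SDs (n−1) and Pearson correlations with
two-sided t-test p-values (flags at p < 0.1 and p < 0.05; zero-variance
series yield NaN, never an exception). Per-cell RMSE maps reduce both
fields by the calibration mode first; cells with observed maximum below
1% are flagged for display masking. The month-of-maximum map takes the
earliest month on ties and flags all-zero cells. Reference-anomaly
correlation maps (e.g. against terrestrial-water-storage anomalies)
require at least 24 overlapping months.

## I/O conventions

Products are yearly NetCDF files, `fwet_[wetland]_max_[sm]_reso025_
[yyyy].nc`, dimensions (lon, lat, time), variable `fwet` as 32-bit float
in [0, 1] with fill value 10²⁰. Time is stored as integer months since
1980-01 (standard calendar); longitudes in [−180, 180), latitudes
ascending. Files are written as classic NetCDF3 so repeated runs with
the same seed produce bit-identical payloads. Reading tolerates
(lat, lon, time) ordering and descending latitudes and canonicalises.
Regridding is conservative (area-weighted, separable in sin-latitude and
longitude for regular grids) for fractions and soil moisture, nearest-
neighbour for categorical fields. CTI subgrids serialise to a ragged
layout (flat pixel arrays plus per-cell index pointers). Every CLI run
writes its resolved YAML config next to its outputs.

## Known limitations

- No catchment-mode TOPMODEL (no streamflow or routing), no CTI from
  DEMs, no sub-monthly stepping, no soil-property variation with depth.
- θ_S uniform over depth is an idealisation carried by the deficit
  formula.
- The 70 cm freeze rule can discard unfrozen shallow layers (see above).
- Whether dynamic-mode calibration should exclude observation months
  flagged frozen is an open choice; all months are scored.
- The synthetic generator does not mimic any specific reanalysis' bias
  structure; conclusions about real-data skill require real inputs.
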