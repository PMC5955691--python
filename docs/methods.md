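# Methods

This note records the modelling choices behind `thermhab`: the statistical
procedure each module implements, the defaults and why they were chosen,
what the synthetic world does and does not emulate, and the numerical
conventions that matter for reproducing results.

## The projection procedure

The pipeline estimates, for each species, where thermally suitable habitat
will be over the 21st century, given (a) where and how abundantly the
species was caught by standardized bottom-trawl surveys, (b) the ocean
temperature history those hauls experienced, and (c) an ensemble of climate
model futures.  Its core assumptions are the usual ones of correlative
niche modelling: the realized niche is stationary in time, temperature
(plus static seafloor structure) is the binding constraint, and species can
occupy any thermally suitable cell — no dispersal limits, fishing,
productivity or carbonate chemistry.  Outputs are therefore projections of
*potential* thermal habitat, not of absolute biomass.

### Two-stage niche model

Occurrence and abundance are modelled separately (a hurdle/delta
formulation): a binomial smooth additive model with logit link for
presence/absence, and a Gaussian model for natural-log biomass density
fitted to positive catches plus pseudoabsence rows.  The prediction is the
product p̂ · exp(ln B̂), which is non-negative by construction and monotone
in each factor.

Both stages share seven predictors — seasonal (3-month) surface and bottom
temperature, annual minimum/maximum bottom and maximum surface temperature
over the trailing 12 months, rugosity, and grain size Φ — plus a
categorical survey term.  Minimum surface temperature is excluded because
it is nearly collinear with minimum bottom temperature; depth is excluded
deliberately so projected distributions are free to deepen as they track
temperature.  The survey factor absorbs between-survey catchability; at
projection time every cell is predicted at a single reference survey level
(the first level alphabetically), which preserves relative spatial pattern
while fixing the catchability scale.

Smooths are penalized cubic B-splines, 5 basis functions per term
(`basis_df`), fitted with `statsmodels` GLMGam.  The penalty weight per
smooth is γ = ln(n)/2, the sample-size-coupled guard against overfitting;
`alpha_scale` (default 1) allows rescaling if a different smoother
implementation is swapped in.  Predictors without enough distinct values to
support a basis (e.g., constant rugosity on a flat synthetic shelf) are
dropped from the smooth set for that fit.

**Extrapolation.**  B-spline bases are undefined outside their knot span,
so each smooth's support is padded by half the training range on each side
at fit time; predictions clip to that padded support.  Within the pad the
fitted outer polynomial pieces extend smoothly, which lets warming
scenarios push beyond observed temperatures (range-expansion behaviour)
without unbounded spline blow-up.  A strict clamp to the training range is
available (`clamp=True`) but off by default.  Pseudoabsence rows
(ln 1e-10 ≈ −23) anchor the biomass surface low outside the observed
range, which is what keeps extrapolated exp(ln B̂) from exploding.

**Determinism.**  Training rows are sorted on (haul_id, species_id) before
fitting, so refitting with permuted input order reproduces predictions
bit-for-bit.

**Validation.**  Rank-based (concordance) AUC of stage-1 predictions on
the held-out chronological 20%, with ties counted ½.  Species below 0.75,
or with a single-class test set, are flagged dropped.

**Recovering a thermal optimum.**  The temperature predictors co-vary
strongly, so a single smooth's partial response splits the thermal signal
across collinear terms.  `thermal_response_profile` instead evaluates the
occurrence model along the realized covariate manifold: the focal
temperature sweeps its observed range while every other predictor follows
its linear regression on the focal temperature.  The profile's argmax is
the recovered optimum; on synthetic species it lands within ~0.5 °C of the
true T_opt at n = 5000.

### Survey preparation conventions

* Pseudoabsence count per (species, never-observed region):
  min(⌊0.10 · hauls in region⌋, ⌊0.10 · total observation records of the
  species⌋), sampled without replacement under a seed.  "Total
  observations" is read as the species' full record count on its coast
  (presences + zeros); floors (not rounding) keep the rule conservative
  and reproducible.  Pseudoabsence rows only ever alter the biomass stage;
  for presence/absence they are indistinguishable from the zero-expanded
  absences they started as.
* Chronological split: within each region, hauls sorted by date with ties
  broken by haul_id; the initial 80% train.  Regions with < 5 hauls go
  entirely to training with a warning.
* Occurrence gate: ≥ 250 presences coastwide, and at least one presence in
  the training split.

### Climate downscaling

Deltas are month-of-year specific: each GCM's baseline is a 12-layer
1995–2014 climatology, so the seasonal cycle of the anomaly is preserved —
necessary because downstream predictors include 12-month extremes.
Regridding is nearest-valid-cell on the sphere (chordal KD-tree, exact for
great-circle nearest), so the regridded field is a permutation with
repetition of native values and never invents data; the fraction of target
cells lying outside the native domain is reported as `filled_fraction`.
The projection grid keeps cells with depth strictly < 401 m ("shallower
than 401 m" read as strict) and labels cells west of −80.75° as Gulf of
Mexico.

### Projection and binning

One summer composite per year: seasonal predictors are the July–September
means, extremes cover October–September.  Bins are 2007–2020 (14 years)
then four 20-year bins to 2100; the named endpoints fix the partition and
the interior edges are the natural 20-year splits.

### Shift geometry

Cell areas use the spherical equal-angle formula A = (R Δφ)(R Δλ cos φ),
R = 6371 km; centroids weight density by area; distances and initial
bearings are spherical (haversine), which differs from ellipsoidal geodesy
by < 0.5% — immaterial at the precision reported.  Longitudes are shifted
to a continuous frame before averaging when a region straddles the
antimeridian (Aleutian-type grids).  Centroids may fall outside the grid
(over land or deep water); that is intended.

### Uncertainty classification

Both screens judge a species' ensemble spread *relative to the whole
species set*, so they are distribution-free in the sense that only ranks
of residuals matter:

* DDU: OLS of ln(SD distance) on ln(mean distance); a species is high
  uncertainty if its residual or its directional disagreement (1 − R)
  strictly exceeds that metric's empirical 95th percentile
  (linear-interpolation convention), medium above the 75th.
* LU: quantile regression (check-loss, `statsmodels` QuantReg) of
  ln(SD Δlat) on ln|mean Δlat| at τ = 0.75 and 0.95; above the 0.95 line
  high, between medium, below low.

Orientation: the text tradition this follows describes flagging species
"above the percentile for directional agreement", which would invert the
meaning of R (R = 1 is unanimity).  The implementation classifies on
disagreement 1 − R so that low agreement ⇒ higher uncertainty, consistent
with R's definition.

Zero shifts are floored (1 km, 0.001°) before logging.  Threshold
exceedance carries a float-noise guard (`isclose` at 1e-9 relative) so
exactly-tied degenerate inputs — all points on one line — rate low rather
than flipping on last-ulp noise.  By construction ~25% of species rate
non-low per criterion: with 878 projections the LU screen leaves ≈ 658 low
and ≈ 45 high, and with independent DDU criteria ≈ 1 − 0.95² ≈ 9.7% (≈ 85)
rate high and ≈ 0.75² ≈ 56% (≈ 494) low.  These counts are what
`scripts/acceptance.py` recomputes.

## The synthetic world

The generator supplies the statistical structure the pipeline assumes,
with known truth for recovery tests:

* **Climatology** — annual-mean surface temperature declining linearly
  with latitude, sinusoidal seasonal cycles (surface peaking in August,
  bottom lagging one month, smaller amplitude), bottom water colder by a
  depth-saturating offset, shared interannual anomalies plus iid monthly
  noise.  Land and off-shelf cells are masked, not removed, so regridding
  is exercised.  Monthly resolution throughout: every downstream quantity
  is a 3-month mean or 12-month extreme, so sub-monthly structure would be
  invisible.
* **GCM ensemble** — each model is the (bias-shifted) climatology plus a
  warming ramp, linear from the baseline midpoint, scaled so the
  2081–2100 minus 1995–2014 difference equals the configured amplitude
  times a latitudinal pattern.  Default amplitudes: ~0.5–1.5 °C
  (strong-mitigation scenario) and ~1.7–4.3 °C (high-emission), matching
  the ~2 °C vs > 4 °C contrast of the scenario pair the labels refer to.
  About a quarter of the models cover only 65–82% of the domain so
  nearest-cell fill is exercised (the real ensembles this emulates needed
  up to ~35% filled).
* **Species** — occurrence probability is prevalence × Gaussian thermal
  suitability exp(−(SBT − T_opt)²/2σ²) (clipped to [0, 1]); positive
  densities are lognormal around max_density × suitability × catchability
  (σ_ln = 0.6).  Bottom temperature is the single dominant niche axis so
  recovery is well-posed; extreme-sensitivity and seafloor-preference
  coefficients exist but default to zero.
* **Surveys** — latitude-banded regions, each with its own catchability
  and season months; only positive catches are exported, as in real survey
  data.

What the generator does **not** emulate: coastline geometry, currents,
eddies, upwelling, spatial autocorrelation of residuals, observation error
in temperature, vessel effects, or species interactions.  Passing tests
therefore demonstrate that the *procedure* is implemented correctly and
recovers known structure under its own assumptions — not that the
assumptions hold for any particular real shelf.

## Problem sizes and defaults

The bundled end-to-end configuration uses a 50 × 40-cell (0.1°) projection
grid on a 5° × 4° shelf, 3 surveys × 25 years × 60 hauls, 20 species,
4 GCMs × 2 scenarios, and full 2007–2100 annual projection — sizes chosen
so a complete run takes about a minute and a half on one CPU while every
stage operates above the degenerate regime (≥ 10 species for percentile
stability, ≥ 2 GCMs for ensemble SDs, ≥ 250 occurrences for gating).
Parameter-recovery studies use 5000 hauls and 10 species.  The
uncertainty-count studies use 878 species projections, the size at which
the classifier count structure (658/45 LU, ~85/~494 DDU) is quoted.

## Known limitations

* The γ = ln(n)/2 penalty enters as a per-term alpha scale for the
  B-spline smoother; other GAM engines couple their complexity penalty to
  selection criteria differently, so deviance-explained values are
  comparable only qualitatively across engines.
* Quantile-regression fits use the default interior-point style solver in
  `statsmodels`; alternative check-loss minimizers can move individual
  borderline points across a quantile line (the count tolerances absorb
  this).
* IDW power (2) and the linear %GSM → Φ rule are field-standard defaults,
  both configurable; no Folk-code handling.
* Ensemble statistics treat GCMs as exchangeable; no weighting by model
  skill or genealogy.
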