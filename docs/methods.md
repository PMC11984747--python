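# Methods

This note records the statistical model, the conventions and numerical
choices behind `venomclim`, what the synthetic generator does and does
not emulate, and the known limitations.

## Bioclimatic indices

Seven indices summarise a 12-month climatology (temperatures in °C,
precipitation in mm; units are enforced by contract, never guessed):

| index | formula | units |
|---|---|---|
| AMT | mean(Tavg₁…₁₂) | °C |
| TAR | max(Tmax) − min(Tmin) | °C |
| AMDTR | mean(Tmaxᵢ − Tminᵢ) | °C |
| I | 100 · AMDTR / TAR | % |
| TS | 100 · SD(Tavg) / (AMT + 273.15) | CV×100 |
| APN | Σ PPTᵢ | mm |
| PS | 100 · SD(PPT) / (1 + APN/12) | CV×100 |

Conventions. TS and PS are coefficient-of-variation forms; temperature
enters the denominator in kelvin so the CV is scale-meaningful, and
precipitation is offset by 1 mm so arid pixels stay finite. SD defaults
to the sample convention (n−1), the default of R's `sd`, with
`sd_denominator="n"` available because the WorldClim production code
uses the population form. WorldClim's distributed BIO4 is plain
SD(Tavg)×100 rather than the CV form; `worldclim_bio4=True` reproduces
it so index values computed here can be compared against downloaded
rasters. I is undefined (missing) when TAR = 0. Tavg defaults to
(Tmax + Tmin)/2 when not supplied. Non-finite monthly inputs raise a
missing-data error at site level and propagate NoData at pixel level.

## Raster handling

Rasters are single-band, float32, north-up, geographic WGS84; any other
CRS is rejected rather than silently reprojected. The pixel footprint is
half-open — [left, right) in longitude, (bottom, top] in latitude — so a
point on a shared edge belongs to exactly one pixel. Point sampling is
nearest-pixel (the value of the containing pixel, no interpolation).
Clipping snaps outward to pixel edges and never resamples; a 10⁻⁹-pixel
tolerance absorbs floating-point noise when a box edge coincides with a
pixel edge. NoData is NaN in memory and a sentinel (−9999) on disk,
carried in the standard GeoTIFF/GDAL tags; round trips are bit-exact for
float32. The subcontinental mapping window is 68.1–97.4 °E,
6.74–35.7 °N.

## Assay reduction

Specific activity is (kinetic rate in AU/min) / (standard-curve slope in
AU/nmol) / (venom mass in mg) → nmol·min⁻¹·mg⁻¹. The kinetic rate is
the OLS slope over all time points rather than a two-point difference:
it uses every reading and is unbiased under i.i.d. absorbance noise.
Negative fitted rates are clipped to zero and flagged. Proteolytic
activity stays on the percent-of-standard scale
(100 · A_sample / A_standard). No blank subtraction is applied before
curve extrapolation; a hook exists if a blank series is available.
Replicates are averaged before modelling; the replicate SD is carried
for reporting only. One-way ANOVA is the classical F test; zero
within-group variance with unequal means reports F = ∞, p = 0.

## Regression procedure

For each activity y and transform τ ∈ {identity, ln, √, 1/y} (τ applied
to the response only; domain violations are errors, never silent
offsets — shifting activities would change the model's meaning):

1. **Full OLS** of τ(y) on the candidate indices with intercept.
   Classical SEs; adjusted R² = 1 − (1−R²)(n−1)/(n−k−1);
   AIC = −2·llf + 2(k+2) on the Gaussian likelihood including constants
   (the `AIC(lm)` convention, counting slopes, intercept and σ). AIC is
   comparable only between models of the same transformed response at
   the same n; cross-transform selection never uses it.
2. **Backward stepwise**: repeatedly drop the predictor with the
   largest t-test p-value above α = 0.05 and refit, until all remaining
   predictors are significant; ties break by column order. An optional
   `protect_adj_r2` mode additionally stops when a drop would lower the
   adjusted R² (equivalently when the dropped predictor has |t| > 1);
   it is off by default because a non-significant predictor with
   |t| > 1 would then block pruning, defeating the purpose of
   eliminating non-significant variables. If everything is eliminated
   an intercept-only fit is returned, flagged.
3. **Diagnostics** on the refined model at α = 0.05:
   Shapiro–Wilk on residuals (N; requires ≥ 8 residuals);
   studentized (Koenker) Breusch–Pagan, LM = n·R² of the auxiliary
   regression of squared residuals on the predictors, p from χ²(k) (H;
   the classic variant is available by flag; exactly constant squared
   residuals short-circuit to LM = 0);
   Rainbow F test comparing the full fit against the fit on the central
   50% of observations ordered by fitted values (L; a perfect fit makes
   it undefined and reports a flagged pass);
   VIFⱼ = 1/(1−R²ⱼ) from regressing predictor j on the rest, threshold
   10 (M).
4. **Downselection**: among cells whose refined model passes N, H and
   L, keeps ≥ 1 predictor, and is significant by the overall F test
   (α = 0.05), the one with the highest adjusted R² wins.
   Multicollinearity is reported but never vetoes: the bioclim indices
   are intrinsically correlated and a well-fitting model may
   legitimately fail M. If no cell qualifies, the card is emitted with
   no selection.

## Geographically weighted regression

A stationarity check, not a predictive replacement: at each site a
weighted least-squares fit with fixed Gaussian kernel
w = exp(−d²/2b²), d in decimal degrees. Bandwidth is either given or
chosen by leave-one-out CV over a 10-point log-spaced grid from the
median nearest-neighbour distance to the extent diagonal. Sites whose
local design is rank-deficient are flagged and excluded from summaries.
The headline summary is the per-predictor ratio SD(local
coefficients)/SE(global coefficient): under a spatially constant truth
it sits well below 1 at moderate bandwidths, and it rises when
coefficients genuinely drift over space. Pointwise local-slope recovery
is *not* asserted anywhere: with ~34 locations and spatially smooth
covariates, a covariate is nearly constant inside a kernel
neighbourhood and its local slope is weakly identified — only the
dispersion signal is reliable at this design size.

## Prediction mapping

The selected model is evaluated per pixel on the aligned covariate
stack and back-transformed naively (exp, square, reciprocal); no
retransformation bias correction (no smearing estimator) is applied,
a deliberate caveat — ln-scale predictions are medians, not means, of
the implied response distribution. NoData in any covariate propagates;
the reciprocal of an exactly-zero linear predictor is NoData, flagged.
Predictions are not clamped to the training range; instead a companion
extrapolation-mask layer marks pixels whose covariates fall outside it,
because a nationwide projection from a few dozen locations extrapolates
heavily. Marginal per-row/per-column mean profiles accompany the grid.
The GeoTIFF is the contract artifact; the blue-to-red PNG is cosmetic.

## Synthetic generator

`synth` fabricates what the pipeline needs, never what it asserts:
smooth monthly fields (low-order trend + seeded Gaussian bumps, a
cosine seasonal cycle, a monsoonal precipitation concentration field)
with tmax ≥ tavg ≥ tmin and ppt ≥ 0 enforced by construction; 34
locations replicated to 115 samples (pooled samples share one jittered
coordinate, so the table has exactly 34 unique points); and activities
τ(y) = β₀ + Σβⱼxⱼ + ε with ε Gaussian, optionally heteroscedastic
(SD rising over the empirical CDF of a chosen covariate — the CDF,
rather than the raw value, makes the violation felt at every site
regardless of the covariate's marginal shape) or spatially correlated
(exponential covariance). Effect sizes are specified per SD of each
covariate and converted to raw-unit coefficients at the sampled sites;
noise is set by a target population R² (default 0.5, matching the mid
range of variance explained one sees in this kind of field data;
0.75 for the deliberately high-SNR variants used in recovery
experiments). Activities violating τ's domain are redrawn and counted;
more than 10% redraws warns that the scenario fights the transform.
Default ranges (base temperature 12–28 °C, seasonal amplitude 2–9 °C,
diurnal range 6–16 °C, annual precipitation 300–2800 mm) give index
magnitudes of subcontinental order on a 40×40 grid of 0.25° pixels
(coarser than 30-arc-second data purely as a sizing choice; all
raster code is resolution-agnostic).

The default truth uses {TS, APN, AMDTR}, a near-orthogonal trio at the
generated sites, so the clean scenario is well conditioned; the
`collinear` preset instead drives the seasonal-amplitude and
diurnal-range fields from the same latent field as the base
temperature, making AMT/TAR/AMDTR/TS strongly collinear (VIFs in the
10²–10⁴ range) to exercise the M gate. What the generator does *not*
emulate: real Indian climatology, biotic drivers (diet, predators,
gene flow), measurement error in coordinates, or assay-level noise
structure — passing tests demonstrate the statistical machinery, not
the ecology.

### Experiment designs fixed in the tests

- Diagnostic calibration: a fixed Gaussian design, n = 200, k = 3,
  2,000 noise redraws; each gate's type-I rate must lie in
  [0.03, 0.07] at α = 0.05. Breusch–Pagan power is measured on the
  heteroscedastic preset (n = 200, SD spanning 1–3σ across a
  covariate's CDF) over 400 regenerated studies.
- Recovery: 500 studies at n = 115 under the high-SNR preset; 95% CI
  coverage of the true coefficients must lie in [90%, 98%], and
  backward elimination must retain exactly the true three predictors
  against one added pure-noise candidate in ≥ 90% of runs. The
  candidate set is the true predictors plus one zero-coefficient
  variable: with c spurious candidates any α = 0.05 elimination retains
  at least one with probability ≈ 1 − 0.95ᶜ, so a seven-candidate
  design caps exact-support recovery near 81% for purely combinatorial
  reasons — the experiment isolates the elimination behaviour instead.
- Transform selection: under log-scale truth the grid must downselect
  the ln cell whenever it selects anything, and select in a majority of
  30 replicates (the gates legitimately reject all cells in a minority
  of draws at α = 0.05).

## Limitations

- The stepwise procedure inherits all the usual post-selection
  caveats: reported p-values and CIs of a selected model are not
  selection-adjusted.
- Adjusted R² is compared across response transforms during
  downselection; R² of τ(y) models are only heuristically comparable
  across τ, which mirrors common practice but is not a formal
  criterion.
- GWR here is diagnostic; no spatial-error or mixed models are fitted.
- Naive back-transformation biases mean predictions low for convex
  inverse transforms (see above).
- CRS support is geographic WGS84 only; kernel distances are in
  degrees, which distorts anisotropically away from the equator —
  acceptable for a subcontinental stationarity check, not for polar
  data.
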