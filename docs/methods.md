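# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic validation does and does not demonstrate.

## 1. Synthetic scenes

The generator emulates a co-registered multi-year monthly raster stack on
an affine grid (no map projection). Each of five base climate variables is

    value(t, y, x) = mean + gradient·(y_norm − ½) + amplitude·seasonal(month)
                     + trend·year + N(0, noise_sd)

with physically nonnegative variables clipped at zero. Evapotranspiration
is *derived* from temperature and precipitation through a fixed monotone
function (a temperature-dependent fraction of precipitation evaporates),
so the attribution model faces realistic collinearity among its features.

Monthly EVI is a baseline plus weighted logistic transforms of temperature
and precipitation, plus rectangular human-trend patches, plus iid Gaussian
noise, clipped to [−0.2, 1]. Temperature carries the larger response
weight, making "temperature is the dominant climate factor" a testable
property rather than an assumption. The decomposition is stored exactly:
any clipping is folded into the stored noise term so

    EVI = climate_component + human_component + noise

holds to machine precision, and the human component is identically zero on
the reserve strip.

Defaults (40 × 40 pixels, 20 years) describe a modestly warming scene:
+0.04 °C yr⁻¹ temperature trend, +0.3 mm month⁻¹ yr⁻¹ precipitation
trend, monthly EVI noise sd 0.02, one greening patch (+0.008 EVI yr⁻¹) and
one degrading patch (−0.006 EVI yr⁻¹), each 10 × 10 pixels, and a
left-edge reserve strip holding 20 % of the grid. Patches with
|trend| ≥ 0.004 EVI yr⁻¹ count as "strong" human signals. The scene-truth
regional human share is defined as Σ|Sen(human)| / Σ(|Sen(climate)| +
|Sen(human)|) over valid pixels — the same slope-weighted aggregate the
attribution stage reports, so truth and estimate are commensurable.

What the scenes do **not** emulate: sensor/compositing artefacts, spatial
autocorrelation of noise, gradual land-use change, lagged vegetation
responses, and drought extremes. Passing recovery tests therefore shows
the *chain* is correct under its own assumptions, not that real-data
attribution is unbiased.

Fractional Gaussian noise for calibrating the Hurst estimator uses
Davies–Harte circulant embedding: the target autocovariance
γ(k) = ½σ²(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is embedded in a
2n-circulant whose FFT eigenvalues are nonnegative for fGn, so every
generated series has the exact covariance at all lags.

## 2. Ecosystem functions

Exact regional parameterisations of the four functions are
application-specific, so each estimator implements the canonical published
form of its family with every coefficient exposed:

* **NPP (CASA light-use efficiency).** Monthly NPP = SSR·FPAR·0.5·ε with
  ε = T1·T2·W·ε_max. FPAR is linear in the vegetation index between
  (0.05, 0.95) and capped at 0.95; T1/T2 are the standard parabola /
  double-logistic temperature-stress scalars around the per-pixel optimal
  temperature (month of greenest vegetation); the water scalar W is an
  input grid, by default 0.5 + 0.5·SM/max(SM) — the moisture-limited
  variant, chosen because no regional evapotranspiration submodel is
  assumed. ε_max defaults to 0.389 g C MJ⁻¹. Annual NPP sums 12 months.
* **Water conservation.** WC = PRE − ET − PRE·c with a per-land-use runoff
  coefficient c; negative balances are floored at zero and flagged, so the
  balance closes as WC + PRE·c + ET − deficit = PRE.
* **Soil retention.** SR = R·K·LS·(1 − C). R follows the Wischmeier
  monthly erosivity formula; LS combines a slope-length term
  (λ/22.13)^m (m stepped 0.2–0.5 by slope, λ = 100 m default) with the
  McCool steepness factor; slope comes from Horn 3 × 3 differences with
  replicated borders. The cover factor is exponential in fractional cover
  with pinned endpoints C(0) = 1, C(1) = 0 (shape parameter α = 2).
* **Habitat quality.** Threat sources are land-use classes; degradation
  D sums weight × distance-decay (linear or exponential, zero beyond the
  threat's reach) × habitat sensitivity, with distances from a Euclidean
  distance transform. HQ = H·(1 − D^z/(D^z + k^z)), z = 2.5, k = 0.5, so
  HQ = H with no threats and exactly H/2 at D = k.

Two utilities support field calibration: the Ångström–Prescott relation
SSR = (a + b·n/N)·Ra with defaults a = 0.25, b = 0.50, and the biomass
conversion carbon = AGB·0.3698 + AGB·4.25·0.4291 (root-to-crown ratio
4.25; above/below-ground carbon coefficients 36.98 % / 42.91 %).

## 3. Index construction

Normalisation is global over each indicator's full space–time record;
per-pixel normalisation is rejected because it erases spatial contrast.
CRITIC weights use pooled pixel-year observations over the valid mask
(population standard deviations; Pearson correlations), computed once for
the whole record and applied to every year. The FVC percentile endpoints
(0.5 / 99.5) are empirical percentiles of all valid EVI values; monthly
cover fractions are clipped to [0, 1] before annual averaging, so the
index is bounded by construction. Water pixels are masked from the
analysis by default (`mask_water`).

Degenerate inputs fail loudly: a constant indicator raises rather than
silently receiving weight 0/0, and collapsed FVC endpoints raise a
degenerate-scene error.

## 4. Trend statistics

* **Theil–Sen**: exact median of all pairwise slopes (even counts average
  the two central values). NaN pixels propagate as NaN in grid mode and
  raise in scalar mode.
* **Mann–Kendall**: S with the tie-corrected variance
  [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18 and the ±1 continuity correction;
  a fully tied series returns Z = 0 and is counted as a tie warning.
* **Hurst (R/S)**: mean rescaled range over non-overlapping blocks at
  log-spaced window sizes, regressed on log window size after dividing by
  the Anis–Lloyd white-noise expectation (H = 0.5 + corrected slope).
  Block dispersion uses the sample standard deviation (ddof = 1), the
  convention under which the Anis–Lloyd expectation centres white noise at
  0.5. The smallest window defaults to max(8, n/32): the very smallest
  blocks carry the worst small-sample distortion, so it grows slowly with
  series length; series shorter than 16 fall back to windows of 4–5 so an
  estimate is still attempted for ≥10-year records. Calibration on exact
  fGn (n = 512, 200 replicates) recovers H = 0.3/0.5/0.8 as
  0.34/0.49/0.72 — within ±0.1, with the known residual shrinkage of R/S
  toward 0.5 at the extremes.
* **Typology**: |Z| ≤ 1.96 is not significant (boundary inclusive), HI =
  0.5 counts as anti-persistent. The unreachable-by-table case of an
  exactly zero slope with significant |Z| is classed "uncertain" with a
  diagnostic flag (no evidence of direction). Thresholds 1.96/1.645 are
  frozen defaults, overridable per call and in the pipeline config.

Annual series (one value per year) are the analysis unit throughout.

## 5. Attribution

Sampling unit: the pixel-year with annual climate aggregates — means for
TEM/WS/SM/SSR, totals for the fluxes PRE/ET. The boosted-tree model
(XGBoost, learning rate 0.3, depth 8, 1000 trees, single-threaded hist for
bit reproducibility) is trained on a random half of the reserve rows and
reported on the held-out half; importances are normalised gain scores.
Hyperparameter search is out of scope — the defaults are treated as given
and exposed in config. A forward-stepwise OLS baseline (entry by adjusted
R² on the training half) shares the split and report schema for
side-by-side comparison.

VEQI_C is predicted for *all* valid pixels from the reserve-trained model
(the standard residual-attribution design), clipped to [0, 1]; VEQI_H is
the unclipped residual and may be negative. Influence degrees pair each
component's Sen slope with the |Z| of the *same* component series — the
only self-consistent pairing. The driver table covers sign-consistent
combinations; because the Sen operator is not additive, inconsistent
combinations are reachable and fall back to the dominant-magnitude
component at 100/0 with a table-gap flag, reported separately. When both
component slopes are exactly zero but the total is not, the pixel gets
driver "none" plus the flag.

The regional summary emits two aggregates of the human contribution: the
mean over attributable pixels, and the slope-weighted share
Σ|Sen(VEQI_H)| / Σ(|Sen(VEQI_C)| + |Sen(VEQI_H)|). The slope-weighted form
is the acceptance comparison against scene truth: on pixels whose true
trend is almost purely climatic, the residual's noise slope makes the
*ratio* aggregate read tens of percent human even when the method is
working correctly, whereas the slope-weighted share weights each pixel by
how much trend it actually carries. Default-scene values: truth 52.3 %,
recovered 46.7 %.

## 6. Pipeline and reproducibility

Stages run in fixed order (simulate → functions → veqi → trends →
attribute) over one working directory; a disabled stage is skipped and a
later stage that misses its inputs raises a dependency error naming the
file. The manifest records a configuration hash (excluding the output
path), per-file SHA-256 checksums, stage wall times and all warning
counters (water-balance floors, Mann–Kendall ties, typology gaps, driver
table gaps). All randomness flows from `numpy.random.default_rng` seeded
from the config, and the NetCDF writer (classic format, scipy engine) is
timestamp-free, so two runs from one configuration are bit-identical —
this is asserted in the test suite, not assumed.

Rasters use a single canonical layout (time, y, x), 0-based indices and
pixel-centre coordinates; VEQI is a fraction internally and percent in
reports. NetCDF is the only raster format.

Problem sizes used by the validation suite — 40 × 40 pixels × 20 years for
recovery and determinism, n = 512 × 200 replicates for Hurst calibration,
10 000 samples for stochastic CRITIC recovery — were chosen so the full
chain, including two complete pipeline runs, executes in well under a
minute while keeping Monte-Carlo error small against the stated
tolerances.

## 7. Known limitations

* The four ecosystem functions are canonical forms, not regional
  calibrations; absolute magnitudes (e.g. t ha⁻¹ of retained soil) should
  not be interpreted without local coefficients.
* R/S Hurst estimates shrink toward 0.5 at extreme H; at 20 annual
  observations the per-pixel index is noisy and only class-level use
  (≶ 0.5) is advisable.
* Residual attribution inherits its identifying assumption: any
  climate-correlated human pressure (or reserve-interior disturbance)
  leaks into the wrong component.
* Boosted trees do not extrapolate; climate conditions outside the
  reserve's feature range are predicted at the range edge.
* No prewhitening is applied before Mann–Kendall; strongly autocorrelated
  series inflate |Z|.
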