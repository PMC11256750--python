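# Methods

`rxsmoke` implements an inference chain that turns raw fire-detection
records and paired chemical-transport-model (CTM) scenario fields into
observation-adjusted prescribed-burn air-quality impacts and attributable
premature deaths. This note documents the models, the defaults and the
numerical choices, and what validation on synthetic data does and does not
demonstrate.

## Study frame

All computations live on a regular planar grid in km (a surrogate for a
4 km CTM projection) with a contiguous daily calendar. The default
synthetic domain is 20 × 20 cells of 4 km over three calendar years
(2015–2017) — large enough for spatial cross-validation, small enough that
the whole pipeline runs in seconds. Two species are carried throughout:
daily-average PM2.5 (μg/m³) and MDA8-O3, the maximum daily 8-hour average
ozone (ppb).

## Prescribed-burn identification

Satellite fire products report detections, not burn types. The classifier:

1. removes detections on agricultural land (field burning is a separate
   source category);
2. clusters the remainder into events: two detections are linked when they
   are within `spatial_radius_km` (default 4 km, one grid cell) **and**
   within `temporal_gap_days` (default 1 day); events are connected
   components of this relation, computed with a k-d tree plus sparse
   connected components and verified in tests against a dense all-pairs
   transitive-closure oracle;
3. labels events by duration: prescribed burns start and end on the same
   day, so single-day events are prescribed and multi-day events wildfires.
   Duration is measured on the whole event — a single-day cluster of many
   detections is still prescribed.

The separation thresholds are configurable defaults, not asserted field
constants. Detected areas of prescribed events are calibrated against
burn-permit records — the more trustworthy area source — by ordinary least
squares of permit area on detected area, matched at grid-cell/day level
and fitted only where permit area is nonzero. Calibrated areas are clamped
at zero; negative burned area is unphysical.

## Scenario differencing

The burn impact is the zero-out difference of two CTM scenario runs,
ΔC_PB(x, t) = C_all(x, t) − C_noPB(x, t), cellwise with sign preserved
(ozone titration can make the impact locally negative).

## Data fusion

CTM output carries multiplicative bias. The fitted bias family is

    obs_m(t) ≈ α_year(y(t)) · [1 + A·cos(2π(doy(t) − t_max)/365.25)] · model_m(t)

with one scale per calendar year, a seasonal cosine of amplitude A < 1
(keeping the correction positive) and peak day t_max, and a period of
365.25 days everywhere. Because the model is bilinear in (α, (A, t_max)),
the fit alternates two exact least-squares steps — annual scales given the
seasonal term, then the cosine/sine coefficients given the scales — until
convergence (tolerance 1e-13, at most 200 iterations). When A = 0 this
reduces to the plain ratio of annual means; a plain ratio alone cannot
recover α exactly when A ≠ 0, because the seasonal term does not average
to exactly zero over a calendar year, which is why the joint fit is used.
A global scale β (the same ratio pooled over all years) is reported as a
diagnostic. Monitor-days with missing observations or with model values at
or below a species floor (0.1 μg/m³ for PM2.5, 1 ppb for O3, configurable)
are excluded; the floors avoid ratio blow-ups over near-zero denominators.

Spatial weighting uses the inter-monitor correlogram: pairwise daily-value
correlations (pairs with ≥ 30 common days) are fitted to exp(−d/L) by
nonlinear least squares, giving an e-folding range L. The static weight
field is w(x) = exp(−d(x)/L) with d(x) the distance from the cell center
to the nearest monitor; monitor positions are snapped to their cell
centers so w = 1 holds exactly at monitor cells. The per-day ratio surface
interpolates the monitor ratios obs/max(model, floor) with the same
exponential kernel, normalized; a day on which no monitor reports gets a
unit surface (pure adjusted model) rather than imputation. The fused field
is

    C_DF(x, t) = w(x)·model(x, t)·ratio_surface(x, t) + (1 − w(x))·α_year·season(t)·model(x, t)

clipped at zero. Ratios rather than raw observations are interpolated so
the product keeps the model's spatial texture while following observed
temporal variation locally.

The observation-adjusted burn impact multiplies the fused total by the
model's cellwise burn fraction:

    ΔC_PB_DF(x, t) = C_DF(x, t) · ΔC_PB(x, t) / C_all(x, t)

and is set to 0 where the model total is at or below the floor. By
construction the burn fraction of the fused field equals the model's burn
fraction wherever defined; negative ozone impacts pass through and are
floored later, at county aggregation.

## Health impact

Excess deaths use the log-linear short-term concentration-response form

    ΔD = D_registered · (1 − exp(−β·ΔC))

applied, by default, to the county annual-mean observation-adjusted impact
(floored at 0) with annual registered cause-specific deaths. Confidence
bounds evaluate the coefficient's interval endpoints; no other uncertainty
is propagated. Because the coefficients describe short-term exposure, a
daily-accumulation variant (summing registered/365.25-scaled daily terms)
is available behind a flag; for the small β·ΔC values involved the two
agree to first order. A gridded variant uses a per-cell population raster
(nearest-neighbour resampled to the concentration grid if needed) and
cause-specific baseline rates; it coincides exactly with the county
variant when exposure, population and rates are uniform.

CR-coefficients are config inputs per pollutant and cause (all-cause,
cardiovascular, respiratory), entered **per unit** (per μg/m³ or per ppb);
published per-10-unit coefficients must be divided by 10, and a validation
guard rejects |β| > 0.1 per unit as a likely unit error. The shipped
defaults are placeholders at typical literature magnitudes for
wildfire-smoke PM2.5 (~1.9%/10 μg/m³ all-cause) and ozone
(~0.43%/10 ppb); replace them for any substantive analysis.

## Evaluation

Metrics: MB = mean(pred − obs); RMSE; NMB = 100·Σ(pred − obs)/Σobs; R² is
the squared Pearson correlation (not 1 − SSE/SST — the two diverge under
bias, so the choice is stated). Missing pairs are dropped pairwise.

Cross-validation refits the entire fusion (bias parameters, correlogram,
weight field, ratio surfaces) per fold on the training observations only:

* k-fold withholding (default 10 folds of 10%) randomly withholds disjoint
  sets of monitor-day observations — the withholding unit is the
  monitor-day;
* leave-one-location-out withholds an entire site per fold, probing
  spatial generalization.

Fused predictions at withheld cells/days are compared with the withheld
observations, per fold and pooled. Emery-style performance criteria are
treated as user-supplied thresholds, not hard-coded.

## Synthetic data

The generator fabricates all six inputs with recorded ground truth:

* **Fires** — events are placed on a lattice of sites ≥ 12 km apart with
  same-site events ≥ 3 days apart, so the default clustering provably
  recovers them; prescribed events are 1–5 same-day detections (areas
  10–300 acres), wildfires span 2–4 days, agricultural detections carry
  the agricultural landcover. Permit areas follow
  1.3·detected + 10 acres + N(0, 5²) by default.
* **Fields** — a positive background (base 8 μg/m³ PM2.5 / 40 ppb O3) with
  a smooth spatial pattern, lognormal AR(1) day-to-day variation and
  spatially correlated anomalies; wildfire plumes enter both scenarios
  (cancelling in the difference); prescribed plumes are truncated
  Gaussians (scale 1.5 cells, cut at 4 cells, 30% next-day carryover,
  amplitude 0.1 μg/m³ per acre for PM2.5 and 0.04 ppb per acre for O3)
  added only to the all-emissions field. The default 400 prescribed events
  over three years put the population-weighted PM2.5 impact near
  0.8–0.9 μg/m³ and O3 near 0.3–0.4 ppb — the magnitude regime of
  Southeastern-US prescribed-burn studies.
* **Monitors** — observations are the model field at the monitor cell times
  the bias family above (defaults α = 1.2, A = 0.2, t_max = day 45),
  plus Gaussian noise truncated at zero. Noise is drawn as
  noise_sd·standard-normal, so for a fixed seed the perturbation scales
  linearly with noise_sd and recovery error degrades monotonically. The
  truncation (rather than a lognormal error) keeps the bias family linear
  and recovery exact in the noise-free limit.
* **Counties** — nearest-seed (Voronoi) regions of random seed cells,
  hence contiguous; a lognormal population raster whose county sums define
  county populations; registered deaths built as cardiovascular +
  respiratory + other at ~0.95%/yr all-cause, so all-cause ≥ CVD +
  respiratory by construction.

**What synthetic validation shows and does not show.** Passing recovery
tests demonstrates that the estimators are correct for data generated by
the assumed families (multiplicative bias, exponential correlogram,
additive plumes). Real observation error is not purely multiplicative,
real plumes are advected and anisotropic, and real county shapes are not
Voronoi cells — so these tests validate the code and the identifiability
of the model, not field performance on real CTM/monitor data.

## Numerical choices and degenerate inputs

* Seasonal phase is recovered from cosine/sine coefficients via atan2,
  mapped into [1, 365.25]; with A ≈ 0 the peak day is unidentifiable and
  its value is arbitrary (amplitude is the meaningful quantity there).
* Correlogram fitting falls back to half the grid span when fewer than two
  usable monitor pairs exist or the fit fails to converge.
* Area calibration rejects designs with a single distinct detected area;
  clustering of an empty list returns an empty list; a monitor with no
  non-missing values is rejected at construction.
* All generators take explicit seeds and are bit-reproducible; the
  pipeline manifest records a config hash and per-artifact SHA-256 so
  reruns can be compared byte for byte.

## Known limitations

No plume dispersion or chemistry (the kernel is a stand-in), no emission
or fuel modelling, no morbidity endpoints, no differential toxicity by
fire type, no kriging variance surfaces, and confidence intervals reflect
CR-coefficient uncertainty only.
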