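# Methods

This note documents the models implemented in `heatecon`, the defaults and
their rationale, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Heatwave detection

**Definition.** TX90p: daily maximum temperature above its calendar-day 90th
percentile for at least 3 consecutive days. Thresholds are ETCCDI-style: for
each calendar day, the percentile is taken over all reference-period values
within a centered window (default 15 days, configurable) pooled across years.
The percentile estimator is linear interpolation between order statistics
(numpy's default, the "type 7" convention), declared so worked examples are
checkable by hand. Exceedance is strict; maximal runs shorter than 3 days are
discarded and runs are *not* merged across single non-exceedance gap days —
the strict consecutive-day reading. Feb 29 uses Feb 28's threshold.

**Regional aggregation.** Detection operates on regional daily Tmax, built as
the population-weighted mean of grid-cell Tmax over each region, with the
same population mask used later for exposure (a single mask, the earliest
snapshot, for the reference period). An area-weighted mean is available by
passing a uniform population.

**Severity.** Wet Bulb Degree-Days: on every heatwave day, the mean over
working hours (9–17 h) of max(0, WBGT_sun − 26 °C), summed per region-year.
The 26 °C threshold is where physiological effects on workers emerge. Hours
outside catalogued heatwave days contribute nothing, and WBDD is additive
over disjoint catalogue splits.

## WBGT formulation

The package computes `WBGT_sun = 0.7·T_nwb + 0.2·T_g + 0.1·T_a` and
`WBGT_shade = 0.7·T_nwb + 0.3·T_a` from its own documented energy-balance
formulation (coefficients in `heat_stress.WBGT_CONSTANTS`):

* **Psychrometric wet bulb**: root of `e_s(T) − e_s(T_d) = A·P·(T_a − T)`
  with Magnus saturation vapour pressure and psychrometric coefficient
  A = 6.6×10⁻⁴ K⁻¹ at standard pressure.
* **Natural wet bulb (sun)**: the same balance plus a solar forcing term
  `γ_r·SR/(1 + c_w·WS)` on the wick (γ_r = 0.015 hPa per W m⁻², c_w = 0.8),
  giving ≈ 2 °C of solar elevation at 800 W m⁻² and 1 m s⁻¹ — the magnitude
  reported for natural-vs-psychrometric wet-bulb differences in full sun.
* **Globe temperature**: `a_g·SR = h_g(WS)·(T_g − T_a) + εσ(T_gK⁴ − T_aK⁴)`
  with effective absorptivity a_g = 0.7, emissivity 0.95 and convective
  coefficient `h_g = 6.3·max(WS, 0.1)^0.6` W m⁻² K⁻¹ (150 mm globe).
* **Shade**: no radiant load, so the natural wet bulb equals the
  psychrometric wet bulb at the fixed 1 m s⁻¹ air movement, and the globe
  term collapses into the air-temperature term.

These choices guarantee the defining limits exactly: at saturation with no
sun both variants return T_a; at SR = 0 and 1 m s⁻¹ sun and shade coincide;
WBGT is monotone in T_a, T_d and SR. Both balances are strictly increasing
and convex in the unknown, so the vectorised Newton iteration (tolerance
10⁻⁴ °C, max 100 iterations, step clipping as damping) converges
monotonically after the first step; tests cross-check it against an
independent bracketed scalar solver of the same equations.

**4+4+4 hourly approximation.** For inputs available only as daily
statistics: hours 12–16 carry the daily maximum, 8–10 and 18–20 the daily
mean, 10–12 and 16–18 their midpoint. Hours outside 8–20 are set to the
daily mean — irrelevant for the 9–17 working day beyond hour 8, but it keeps
a full 24-hour contract with the profile bounded by [mean, max].

## Bias correction

Empirical quantile mapping per variable (the WBGT *inputs*, not the index
itself), fitted on the calibration overlap of observed and modelled daily
series: 99 percentile pairs (1–99, linear estimator) per calendar-month
window by default, both configurable. Application interpolates linearly
between fitted pairs; outside the calibrated range the boundary correction
is applied as a constant offset. The map is order-preserving, and applying
it to the calibration model quantiles reproduces the observed quantiles to
machine precision (a test invariant).

## Exposure and the annual shock

Workability functions and constants are given in the README; the
implementation notes are:

* ISO/NIOSH ramps are clamped to [0, 1]; Hothaps is clamped to 1 for
  non-positive WBGT (the logistic's analytic limit) and floors at 0.1.
* The working day "9 h to 17 h" is read half-open: hours 9…16, eight hourly
  values, averaged arithmetically.
* Outdoor sectors use WBGT_sun, indoor sectors WBGT_shade; the
  sector → (workload class, indoor/outdoor) map is part of the economy
  configuration.
* Only heatwave days contribute losses: the pipeline quantifies extreme-heat
  impacts, not mean-warming impacts, so a hot day outside a catalogued event
  adds nothing.
* Annualisation: `τ_rs = Σ_q w_qrs · (Σ_{d∈q} loss_rsd)/D_q` with D_q the
  Mon–Fri days of quarter q and w_qrs quarterly activity shares (uniform ¼
  by default). This concrete normalisation — losses per quarterly working
  day, weighted by when the sector's activity happens — is one reading of
  "annual-equivalent" aggregation; it is isolated in `annualize_shock` so
  alternative readings are pluggable. It is linear in daily losses and in
  the weights, and τ = 0 for heatwave-free years.

Population weighting regrids the climate field to the population grid by
nearest neighbour, interpolates population linearly between snapshot years
(clamped outside the snapshot span), and averages over cells whose centers
fall in the region polygon; a zero-population region falls back to the
unweighted mean with a warning.

## The general-equilibrium model

A comparative-static, single-period, multi-region multi-sector model:

* **Technology**: Leontief between intermediates and value added; value
  added `VA = [δ_K (χK)^ρ + δ_L (ψL)^ρ]^{1/ρ}`, ρ = (σ_s−1)/σ_s, in
  calibrated-share form. The heat shock is labour-augmenting:
  ψ′ = (1−τ)ψ.
* **Trade**: one Armington composite per (destination, good) serving both
  intermediate and final use, CES (σ_ARM, default 2.0) between the domestic
  variety and an import aggregate; the aggregate is sourced across origins
  through a CRESH nest with per-source elasticities σ_IMP (default 5.0
  cross-country, ×1.2 within-country — the border effect). CRESH demands are
  solved from the implicit aggregator by a bracketed scalar root per nest;
  with equal elasticities the nest provably collapses to CES, which is its
  test oracle. Source elasticities are restricted to σ_IMP > 1, keeping the
  implicit weights positive.
* **Demand and closure**: the regional household earns all factor income,
  saves a fixed share (investment demand spent locally with benchmark
  shares), and consumes with Cobb-Douglas shares. Factor endowments are
  fixed, fully employed, mobile across sectors but not regions. Numeraire:
  region 0's factor-price index.
* **Value-added elasticity** σ_s defaults to 0.8 (capital–labour
  substitution below unity, the common range for short-run calibrations);
  σ_s = 1 is handled as the exact Cobb-Douglas limit.

**Solution.** Unknowns are log prices (domestic goods, regional wage and
rent). Equations: zero profit per activity, factor-market clearing per
region, with one redundant equation (Walras's law) replaced by the
numeraire. Goods markets clear by construction: at candidate prices, gross
outputs solve the linear system X = T(p)·(A·X + F(p)), where T collects
Armington/CRESH sourcing shares and A the Leontief coefficients. The root
solve (MINPACK hybrid on log prices, benchmark initialisation) must reach a
max residual below 10⁻⁸; the dropped market's residual is reported as the
Walras diagnostic. Real GDP is the sum of sectoral value-added quantities at
benchmark prices, so the sectoral decomposition of regional GVA changes is
exact by construction.

Analytic anchors tested: calibration replicates the SAM at unit prices to
< 10⁻⁸; a one-sector Cobb-Douglas economy under shock τ changes real GDP by
exactly (1−τ)^θ (θ the labour value share); autarkic regions are unaffected
by foreign shocks; higher trade elasticities weakly buffer the shocked
region's loss.

## Synthetic data

The generator emulates the *structure* of the study inputs, not any real
geography or climate statistics:

* **Meteorology**: per cell, temperature = annual mean + seasonal sinusoid
  (peak mid-July, default amplitude 10 °C) + AR(1) daily anomaly (default
  s.d. 2 °C, lag-1 correlation 0.7 — persistence makes multi-day exceedance
  runs possible) + diurnal sinusoid (peak 15 h, default 5 °C) ; dew point is
  temperature minus a daily Gamma-distributed depression whose mean falls
  with a "maritime" parameter, guaranteeing T_d ≤ T_a by construction; solar
  radiation is a clear-sky day-length-modulated sinusoid, zero at night;
  wind is lognormal around 2 m s⁻¹. One seeded generator per run; the seed
  is recorded in the output attributes and the run manifest.
* **Hot spells** are injected by raising every hour of the affected days by
  a block or triangular amplitude profile, so daily Tmax rises by exactly
  the profile — enabling exact injection-recovery tests of the detector.
* **Population**: a lognormal spatial pattern (concentration = log-s.d.),
  scaled by constant growth across snapshot years.
* **Toy economies**: regions with identical sector lists (default:
  agriculture and construction outdoor/high-and-moderate workload,
  manufacturing and services indoor), intermediate-cost share `io_density`,
  import share `trade_openness` sourced uniformly from other regions, fixed
  saving rate. Gross outputs are the Perron eigenvector of the
  value-conserving demand-share matrix, which makes the SAM balance to
  machine precision *by construction* rather than by RAS-style adjustment.

What passing tests therefore show: the algorithms are correct on inputs with
realistic structure (seasonality, persistence, humidity coupling, balanced
accounts). What they do not show: skill on real reanalysis fields (no
spatial correlation of anomalies across cells, no weather regimes, no
orography), real population change, or real SAM asymmetries;
continental-scale headline numbers require the real data sources and are out
of scope here.

## Problem sizes and degenerate inputs

Defaults throughout are chosen so a full pipeline run (multi-year hourly
meteorology on a few-cell grid, a handful of regions and sectors) completes
in seconds and the reference-quantity script (30-year thresholds, 1,000
detector years) in under a minute — sizes a reviewer can re-run casually
while exercising every code path. Degenerate inputs are contracts, not
accidents: zero noise and amplitude give exactly constant temperature; a
constant reference series gives constant thresholds under any window;
identity quantile maps change nothing; zero openness gives exact autarky;
τ = 0 reproduces the benchmark equilibrium bit-for-bit. NaNs in any stage
artifact abort the pipeline run.

## Known limitations

* The WBGT energy-balance coefficients are a documented in-package
  formulation satisfying the index's defining limits and monotonicities, not
  a re-implementation of any published coefficient set; absolute WBGT levels
  may differ from other implementations by a few tenths of a degree.
* Quarterly weights default to uniform; real seasonal activity patterns
  (e.g. agriculture concentrated in Q2–Q3) must be supplied by the user.
* The CGE model is deliberately compact: no taxes, no government, no
  international capital flows, one household per region, saving-driven
  investment. It propagates sectoral productivity shocks; it is not a
  forecasting model.
* Workability heterogeneity within sectors, adaptation (air conditioning,
  task rescheduling) and heat-induced occupational injuries are not
  modelled.
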