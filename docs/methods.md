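# Methods

This note documents the models, conventions and design choices behind
`bambooflux`, and what the synthetic-data tests do and do not establish
about real tower data.

## Conventions

* **Sign.** NEE < 0 is net uptake (carbon sink); RE ≥ 0; GEP = RE − NEE is
  the conservation identity that holds exactly at every record and every
  aggregation level.
* **Day/night.** A half hour is night when PAR < 5 μmol m⁻² s⁻¹. The
  threshold is not printed metadata of the original study; 5 μmol m⁻² s⁻¹
  is standard flux-community practice and robust to sensor noise near
  dawn. The synthetic forward model applies the same convention (no uptake
  below the threshold), which keeps "RE = NEE at night" exact in the
  simulated world.
* **Units.** Half-hourly fluxes are mg CO₂ m⁻² s⁻¹; sums are gC m⁻²,
  converted only at aggregation (× 1800 s × 12/44 ÷ 1000 per record).
  α is fitted in mg CO₂ μmol⁻¹ and reported ×1000 in μg μmol⁻¹. VPD is
  generated and analyzed in hPa.

## Quality control

The u\* filter (default threshold 0.2 m s⁻¹) applies to nighttime records
only: weak nocturnal turbulence causes the underestimation the filter
exists to remove, and daytime turbulence is not the stated problem.
Whether the paired daytime record should also be removed, and how storage
flux was treated, is unknown for the original record; both are omitted.

Meteorological gaps ≤ 4 records (2 h, boundary inclusive) with
observations on both flanks are linearly interpolated. Longer gaps — and
short gaps touching a series boundary — use the MDV estimate over the same
half-hour slot within ±7 days, computed from *originally observed* values
only. This makes filling idempotent and order-independent, and makes the
MDV fill exact (to float precision) on any signal with a pure 24-hour
period. The ±7-day window is a config knob; 7 days is the common default.
Slots whose MDV window holds no observation remain missing and are logged.
NEE gaps are never filled here; they are model-filled during partitioning
so their provenance (`gapfilled_model`) is distinguishable.

## Lloyd–Taylor respiration

RE(Ts) = R_ref · exp(E0 · (1/(T_ref − T0) − 1/(Ts_K − T0))) with the
original formulation's constants T_ref = 283.15 K and T0 = 227.13 K, fitted
to u\*-accepted, observed nighttime NEE–Ts pairs by bounded trust-region
least squares (R_ref ∈ (0, 10], E0 ∈ (0, 1000]; three-point multi-start).
Soil temperature at the shallowest depth drives the model, as it co-varies
most with surface respiration. The fit scope is the calendar year; fits
with fewer than 10 pairs or with soil-temperature range under 1 K (E0
unidentifiable) are flagged and fall back to the global fit. Fit windows
narrower than a season would track seasonal R_ref drift but were not
needed for the synthetic conditions.

## Light-response windows

The year splits into 73 consecutive 5-day windows anchored at Jan 1; the
73rd absorbs the remainder (5 days in common years, 6 in leap years), so
the windows always partition the year. Each window's daytime observed
records are fitted to −NEE = α·PAR·Pmax/(α·PAR + Pmax) − RE with bounds
α ∈ (1e-5, 0.05] mg μmol⁻¹, Pmax ∈ (0.01, 5], RE ∈ [0, 2] and start values
(0.002, 0.5, 0.1). RE is a free third parameter — that is what fitting the
full equation to daytime data means — and can be cross-checked against the
Lloyd–Taylor prediction as a diagnostic.

A window fit is flagged (excluded from the seasonal series and from
period statistics) when any of these hold:

* fewer than 20 daytime samples (≥ 6 residual degrees of freedom per
  parameter);
* no radiation spread (PAR range < 50 μmol m⁻² s⁻¹ — α and Pmax jointly
  unidentifiable);
* α or Pmax pinned at a bound;
* the Gauss–Newton standard error of α or Pmax exceeds 50 % of the
  estimate. This last rule matters in winter: windows that never approach
  light saturation cannot constrain Pmax, and the unconstrained estimates
  are biased high by factors of 2–3. With the rule, fitted window Pmax
  tracks the generating seasonal trajectory with r ≈ 0.99 at noise
  sd 0.05; without it, r ≈ 0.92.

The α/Pmax trend uses a Gaussian kernel of σ = 2 windows (10 days; the
bandwidth is a config knob since only the filter type is canonical),
implemented as normalized convolution: flagged windows carry zero weight
and the kernel renormalizes, so constants are preserved exactly and gaps
do not drag the trend toward zero.

## Model filling and partitioning

Nighttime NEE gaps take the Lloyd–Taylor prediction at the record's soil
temperature; daytime gaps take the covering window's hyperbola at the
record's PAR (nearest converged window when the covering fit failed, with
the fallback counted in the log). Nighttime fills are exactly recoverable
in the noiseless synthetic world; daytime fills carry the window-constant
RE offset and therefore match a Ts-varying truth only to within that
offset's within-window variation (~0.01–0.03 mg m⁻² s⁻¹) — an inherent
property of the window-based method, not an implementation artifact.

Partitioning: nighttime RE is the measured NEE itself; daytime RE is the
Lloyd–Taylor prediction; GEP = RE − NEE everywhere, which makes nighttime
GEP identically zero. Partial first/last days are excluded from daily
sums; 5-day sums follow the light-response windows.

## Phenology

The six-period calendar (FG_ON, LS_ON, NF_ON, LR_OFF, LS_OFF, NF_OFF) is a
required input: dated FG/LS/LR intervals per year plus each year's on/off
class, with NF as the implicit remainder, so labeling partitions every
covered year. The synthetic calendar places FG in April and LS in May–June
for on-years, LR in April–mid-May and LS in mid-May–July for off-years —
plausible subtropical dates, since the original period dates are not
published. 5-day blocks take their majority-day label, ties breaking
toward the earlier period in the cycle. Period statistics are computed on
the 5-day series (the resolution at which Pmax exists, and the scale of
the published per-period sums) with population sd (a single-block stratum
reports sd = 0).

## Driver analysis

Pearson correlations use pairwise-complete observations per stratum with
two-sided t-test p-values and the conventional `*`/`**` flags at 0.05 /
0.01. Path analysis is classic per-equation standardized OLS over the
fixed acyclic graph {VPD, Prec, PAR, LAI, Ta, Ts} → Pmax; the same six →
RE; Pmax → GEP; {GEP, RE} → NEE, estimated within each stratum after
z-standardization with listwise deletion; full-information SEM estimation
is deliberately out of scope, as per-equation OLS is the reproducible
baseline and the exogenous factors covary freely. Coefficients beyond |1|
are possible under collinearity (suppression) and are flagged, not
clipped; a numerically singular design falls back to a ridge penalty of
1e-8 with a warning. Strata with n < 15 are refused. Indirect
factor→NEE effects are the exact products along the photosynthetic chain
PC(f→Pmax)·PC(Pmax→GEP)·PC(GEP→NEE) and the respiration chain
PC(f→RE)·PC(RE→NEE).

The structural simulator used in tests builds each endogenous variable
with error variance chosen so its population variance is exactly 1, making
the supplied coefficients the true standardized path coefficients.

## Synthetic generator: what it emulates, and what it does not

Emulated: subtropical monsoon seasonality (annual Ta cycle ~5–28 °C around
a 16.6 °C mean, damped and lagged soil temperature, ~1400–1800 mm yr⁻¹
precipitation concentrated in summer, seasonal daylength and PAR with
daily cloudiness); the stand's photosynthetic phenology (seasonal Pmax
0.30–0.70 mg m⁻² s⁻¹ base with an off-year leaf-spreading peak to ~0.9 and
a bimodal on-year pattern, α 2.4–3.4 μg μmol⁻¹ in antiphase with Pmax,
matching the observed negative α–Pmax association); Lloyd–Taylor
respiration (R_ref = 0.075 mg m⁻² s⁻¹, E0 = 308.56 K); additive Gaussian
NEE noise (default sd 0.05 mg m⁻² s⁻¹); random gaps of mixed lengths; and
injected low-u\* night episodes with NEE suppressed ×0.5 — a magnitude
chosen only to produce the underestimation the filter must remove.

Not emulated: radiative-transfer or energy-balance realism, storage and
advection, weather fronts and heat waves, instrument drift. Baseline
nighttime u\* is drawn in [0.25, 0.80] m s⁻¹ — above the rejection
threshold — so low-turbulence conditions exist exactly where injected;
this is what lets the u\*-filter tests demand an exact match against the
injection mask rather than a statistical one. The resulting annual sums
(NEE ≈ −450, RE ≈ 1200, GEP ≈ 1650 gC m⁻² a⁻¹) are weaker than the real
stand's (≈ −1060 / 1790 / 2850): a plain rectangular hyperbola with
realistic Pmax cannot reach the observed summer GEP density, so the
simulator reproduces the *structure* of the seasonal and phenological
pattern (LS periods as the strongest 5-day sinks, off-year LS strongest,
temperature-dominated driver ranking), not the absolute magnitudes.
Passing tests therefore certify the correctness of the algorithms —
recovery of known parameters, exactness of fills and identities,
determinism — and say nothing about sensor-level error structure in real
data.

## Numerical choices

* Optimizers: SciPy bounded trust-region least squares with
  xtol = ftol = gtol = 1e-14, so noiseless parameter recovery reaches
  1e-6 relative or better.
* Gaussian smoothing truncates the kernel at 4σ (SciPy default); the
  normalized-convolution ratio cancels the truncation mass.
* CSV output uses 10 significant digits, which makes identical runs
  byte-identical while keeping round-trip error (~1e-7 on annual sums
  through a write/read cycle) far below any tolerance used.
* Degenerate inputs are refusals or flags, never silent: negative
  thresholds, overlapping gap specifications, constant soil temperature,
  constant-PAR windows, empty MDV windows, sub-minimum strata.

## Known limitations

* Single-tower, single-climate generator; no cross-site generality.
* The Lloyd–Taylor scope is annual; real seasonal acclimation of R_ref
  would be absorbed into residuals.
* Daytime model fills inherit the window-constant RE approximation
  (above).
* Path analysis quantifies linear standardized associations on the fixed
  graph; it does not test the graph itself, and no significance testing of
  indirect effects is performed.
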