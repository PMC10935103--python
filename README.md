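# bambooflux

Eddy-covariance carbon flux analysis for a subtropical Moso bamboo
(*Phyllostachys edulis*) forest, built as a fully testable pipeline: every
processing stage that turns raw half-hourly tower records into phenology-
resolved carbon budgets and driver attributions is implemented as a library
function, exercised by numbered analysis scripts, and verifiable against a
synthetic tower-data generator with known ground truth.

Moso bamboo stands alternate between *on-years* (mass bamboo shoot
production and "explosive" culm growth) and *off-years* (few shoots, leaf
renewal on established culms). The package segments the full phenology
cycle into six periods — FG_ON (fast culm growth), LS_ON / LS_OFF (leaf
spreading), LR_OFF (leaf renewal), and the remaining normal days NF_ON /
NF_OFF — and quantifies how carbon fluxes and photosynthetic capacity vary
across them and what drives that variation.

## The processing chain

1. **Quality control** (`bambooflux.qc`). Nighttime records with friction
   velocity u\* < 0.2 m s⁻¹ are rejected (weak turbulence pools respired
   CO₂ below the canopy and biases nighttime NEE low). Meteorology gaps of
   ≤ 2 h are linearly interpolated; longer gaps take the mean-diurnal-
   variation (MDV) estimate — the mean of observations at the same half
   hour within ±7 days.
2. **Partitioning** (`bambooflux.partition`). Because there is no
   photosynthesis in the dark, nighttime NEE *is* ecosystem respiration, so
   the Lloyd–Taylor model

   ```
   RE(Ts) = R_ref · exp( E0 · ( 1/(T_ref − T0) − 1/(Ts_K − T0) ) )
   ```

   (T_ref = 283.15 K, T0 = 227.13 K) is fitted to u\*-accepted nighttime
   NEE against soil temperature. NEE gaps are model-filled (night:
   Lloyd–Taylor; day: the covering light-response fit), daytime RE is
   predicted from the model, GEP = RE − NEE everywhere, and half-hourly
   fluxes accumulate to daily / 5-day / annual sums in gC m⁻²
   (12/44 mass conversion at aggregation). Negative NEE is a carbon sink.
3. **Light response** (`bambooflux.lightresponse`). In each of 73
   non-overlapping 5-day windows per year, daytime NEE is fitted to the
   rectangular hyperbola

   ```
   −NEE = α·PAR·Pmax / (α·PAR + Pmax) − RE
   ```

   yielding the apparent quantum efficiency α (reported in μg μmol⁻¹) and
   maximum photosynthetic rate Pmax (mg CO₂ m⁻² s⁻¹); the series is
   Gaussian-smoothed (σ = 2 windows) to show the seasonal trend.
4. **Phenology statistics** (`bambooflux.phenology`). Each 5-day block gets
   its majority-day period label from a dated calendar, and mean ± sd of
   NEE, RE, GEP, Pmax, α are computed per period.
5. **Driver attribution** (`bambooflux.drivers`). Pearson correlations and
   classic path analysis (per-equation standardized OLS) on the 5-day
   series relate six factors — VPD, precipitation, PAR, LAI, air and soil
   temperature — to the fluxes through two causal chains:
   factors → Pmax → GEP → NEE and factors → RE → NEE; indirect effects are
   the products of the direct coefficients along each chain.

The synthetic generator (`bambooflux.synthetic`) emulates the subtropical
monsoon climate and the stand's photosynthetic phenology (off-year leaf
spreading carries the uptake peak; on-years are bimodal), drives NEE
through the same forward model, and injects gaps and low-u\* episodes with
a truth mask, so every stage above has a parameter-recovery oracle.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_qc_gapfill.py
python analysis/03_light_response.py
python analysis/04_partition_fluxes.py
python analysis/05_phenology_stats.py
python analysis/06_driver_analysis.py
```

The five-year synthetic run (on-years 2011/2013/2015) prints, among others:

```
2011: Lloyd-Taylor r_ref=0.0744 E0=308.0 K (n=7515)
2011: NEE -439, RE 1199, GEP 1637 gC m-2 a-1 (sink: NEE < 0)

mean NEE per period (gC m-2 per 5 days):
  FG_ON     -14.23 +/- 1.70 (n=18)
  LS_ON     -13.25 +/- 2.05 (n=36)
  NF_ON      -3.53 +/- 3.13 (n=165)
  LR_OFF    -11.62 +/- 2.47 (n=18)
  LS_OFF    -16.00 +/- 3.68 (n=31)
  NF_OFF     -2.83 +/- 2.40 (n=97)
strongest 5-day sink stratum: LS_OFF

dominant driver of NEE in the synthetic stand: ts
```

Reading this: the fitted Lloyd–Taylor parameters recover the generator's
truth (R_ref = 0.075 mg CO₂ m⁻² s⁻¹, E0 ≈ 309 K); every simulated year is
a net carbon sink; the leaf-spreading periods are the strongest 5-day
sinks, with the off-year leaf spreading (LS_OFF) strongest of all; and the
path analysis identifies soil temperature (with air temperature opposing)
as the dominant driver of NEE — the same qualitative structure reported
for the real stand. The magnitudes are smaller than the real site's
because the simulator's light-response envelope is conservative (see
`docs/methods.md`).

The same chain runs as one command from a YAML config:

```
bambooflux simulate --years 2 --seed 7 --out syn/
bambooflux run-all --config cfg.yaml --out results/
```

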