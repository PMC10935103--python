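"""Synthetic half-hourly tower data with known generating truth.

The generator emulates a subtropical monsoon flux site: seasonal and diurnal
cycles of PAR, air and soil temperature, VPD and precipitation, and an NEE
series built from the rectangular-hyperbola light response plus Lloyd-Taylor
respiration,

    NEE = RE(Ts) - alpha*PAR*Pmax / (alpha*PAR + Pmax) + eps,

with additive Gaussian noise ``eps``.  True RE and GEP (the hyperbola term)
are retained per record so every downstream stage has a parameter-recovery
oracle.  Gaps of mixed lengths and low-turbulence (low u*) nighttime episodes
with suppressed NEE can be injected on top, together with a truth mask of the
altered indices.

Baseline nighttime u* is drawn above the standard 0.2 m s-1 rejection
threshold; low-u* conditions appear only where injected, so the set of
records a u* filter must reject is exactly the injection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (
    DATA_COLUMNS,
    NIGHT_PAR_THRESHOLD,
    QC_MISSING,
    QC_OBSERVED,
    RECORDS_PER_DAY,
    half_hourly_index,
    is_night,
)

__all__ = [
    "ClimateConfig",
    "TrueParameterTrajectory",
    "generate_meteorology",
    "generate_fluxes",
    "inject_gaps_and_low_ustar",
    "generate_dataset",
    "seasonal_trajectory",
    "synthetic_lai",
]


@dataclass(frozen=True)
class ClimateConfig:
    """Climate of the simulated site (subtropical monsoon defaults).

    Temperatures in deg C, PAR in umol m-2 s-1, precipitation in mm per wet
    half hour, u* in m s-1.  Soil temperature is a damped, lagged copy of the
    air-temperature annual cycle, as observed at shallow depth.
    """

    ta_mean: float = 16.6
    ta_seasonal_amp: float = 11.0
    ta_diurnal_amp: float = 4.0
    ta_noise_sd: float = 1.2
    ts_damping: float = 0.65
    ts_lag_days: float = 15.0
    ts_diurnal_amp: float = 1.2
    ts_noise_sd: float = 0.4
    par_peak_winter: float = 700.0
    par_peak_summer: float = 1600.0
    daylength_mean_h: float = 12.0
    daylength_amp_h: float = 2.2
    rh_mean: float = 0.76
    rh_diurnal_drop: float = 0.12
    rh_noise_sd: float = 0.06
    prec_prob_winter: float = 0.02
    prec_prob_summer: float = 0.05
    prec_mean_mm: float = 2.5
    ustar_night: tuple[float, float] = (0.25, 0.80)
    ustar_day: tuple[float, float] = (0.15, 0.90)


@dataclass
class TrueParameterTrajectory:
    """Generating truth for the flux forward model.

    ``alpha_daily`` (mg CO2 per umol photons) and ``pmax_daily``
    (mg CO2 m-2 s-1) hold one value per simulated day; ``r_ref`` and ``e0``
    are the Lloyd-Taylor parameters shared across the run.  ``gap_spec`` is a
    list of ``(variable, start_index, length)`` windows to blank out;
    ``low_ustar_fraction`` is the share of nighttime records turned into
    low-turbulence episodes.
    """

    alpha_daily: np.ndarray
    pmax_daily: np.ndarray
    r_ref: float = 0.075
    e0: float = 308.56
    noise_sd: float = 0.05
    gap_spec: list[tuple[str, int, int]] = field(default_factory=list)
    low_ustar_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_daily = np.asarray(self.alpha_daily, dtype=float)
        self.pmax_daily = np.asarray(self.pmax_daily, dtype=float)
        if self.alpha_daily.shape != self.pmax_daily.shape:
            raise ValueError("alpha_daily and pmax_daily must have equal length")
        if (self.alpha_daily <= 0).any() or (self.pmax_daily <= 0).any():
            raise ValueError("alpha and pmax trajectories must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.low_ustar_fraction <= 1.0:
            raise ValueError("low_ustar_fraction must lie in [0, 1]")

    @classmethod
    def constant(
        cls,
        days: int,
        alpha: float = 0.0025,
        pmax: float = 0.6,
        **kwargs,
    ) -> "TrueParameterTrajectory":
        """Time-invariant parameters, handy for exact recovery tests."""
        return cls(
            alpha_daily=np.full(days, alpha),
            pmax_daily=np.full(days, pmax),
            **kwargs,
        )


def _doy(index: pd.DatetimeIndex) -> np.ndarray:
    return index.dayofyear.to_numpy().astype(float)


def _season_weight(doy: np.ndarray) -> np.ndarray:
    """0 in midwinter, 1 at the summer peak (day-of-year ~203)."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * (doy - 22.0) / 365.25))


def generate_meteorology(
    days: int,
    seed: int,
    climate: ClimateConfig | None = None,
    start: str | pd.Timestamp = "2011-01-01",
) -> pd.DataFrame:
    """Generate a half-hourly meteorology series (fluxes unset).

    Deterministic for a fixed ``seed``.  PAR follows a diurnal half-sine that
    is zero at night with a seasonal peak and daily cloudiness; Ta/Ts follow
    annual plus diurnal sinusoids with Ts damped and lagged; VPD is derived
    from Ta via the Magnus saturation pressure and a fluctuating relative
    humidity; precipitation is a sparse event process.
    """
    cfg = climate or ClimateConfig()
    index = half_hourly_index(start, days)
    rng = np.random.default_rng(seed)
    n = len(index)
    doy = _doy(index)
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day_ordinal = np.arange(n) // RECORDS_PER_DAY
    w = _season_weight(doy)

    # --- PAR: seasonal half-sine daylight arch x daily cloudiness
    daylength = cfg.daylength_mean_h + cfg.daylength_amp_h * np.sin(
        2 * np.pi * (doy - 80.0) / 365.25
    )
    sunrise = 12.0 - daylength / 2.0
    peak = cfg.par_peak_winter + (cfg.par_peak_summer - cfg.par_peak_winter) * w
    phase = (hour - sunrise) / daylength
    arch = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
    clearness_daily = rng.beta(5.0, 1.2, size=days)[day_ordinal]
    jitter = np.clip(1.0 + 0.08 * rng.standard_normal(n), 0.0, None)
    par = np.clip(peak * arch * clearness_daily * jitter, 0.0, None)

    # --- air and soil temperature
    annual = -np.cos(2 * np.pi * (doy - 22.0) / 365.25)  # peak ~day 203
    diurnal = -np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    ta_noise = _ar1(rng, n, 0.95, cfg.ta_noise_sd)
    ta = (
        cfg.ta_mean
        + cfg.ta_seasonal_amp * annual
        + cfg.ta_diurnal_amp * diurnal
        + ta_noise
    )
    annual_lag = -np.cos(2 * np.pi * (doy - 22.0 - cfg.ts_lag_days) / 365.25)
    ts_diurnal = -np.cos(2 * np.pi * (hour - 16.0) / 24.0)
    ts = (
        cfg.ta_mean
        + cfg.ts_damping * cfg.ta_seasonal_amp * annual_lag
        + cfg.ts_diurnal_amp * ts_diurnal
        + _ar1(rng, n, 0.98, cfg.ts_noise_sd)
    )

    # --- precipitation: sparse events, wetter in summer
    prec_prob = cfg.prec_prob_winter + (cfg.prec_prob_summer - cfg.prec_prob_winter) * w
    wet = rng.random(n) < prec_prob
    prec = np.where(wet, rng.exponential(cfg.prec_mean_mm, size=n), 0.0)

    # --- VPD from Magnus saturation pressure (hPa) and relative humidity
    es = 6.112 * np.exp(17.62 * ta / (243.12 + ta))
    rh = (
        cfg.rh_mean
        - cfg.rh_diurnal_drop * np.clip(diurnal, 0.0, None)
        + cfg.rh_noise_sd * rng.standard_normal(n)
    )
    rh = np.where(wet, 0.97, rh)
    rh = np.clip(rh, 0.30, 1.00)
    vpd = np.clip(es * (1.0 - rh), 0.0, None)

    # --- friction velocity: baseline turbulence above the rejection threshold.
    # Night here must match the filter's criterion (PAR < 5) so that low-u*
    # nights exist only where explicitly injected.
    night = par < 5.0
    lo = np.where(night, cfg.ustar_night[0], cfg.ustar_day[0])
    hi = np.where(night, cfg.ustar_night[1], cfg.ustar_day[1])
    ustar = rng.uniform(lo, hi)

    out = pd.DataFrame(
        {
            "nee": np.nan,
            "par": par,
            "ta": ta,
            "ts": ts,
            "vpd": vpd,
            "prec": prec,
            "ustar": ustar,
            "qc": QC_OBSERVED,
        },
        index=index,
    )
    return out


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return x


def light_response(par, alpha, pmax):
    """Rectangular-hyperbola gross uptake: alpha*PAR*Pmax/(alpha*PAR + Pmax)."""
    par = np.asarray(par, dtype=float)
    return alpha * par * pmax / (alpha * par + pmax)


def lloyd_taylor_re(ts_c, r_ref, e0, t_ref=283.15, t0=227.13):
    """Lloyd-Taylor respiration at soil temperature ``ts_c`` (deg C)."""
    ts_k = np.asarray(ts_c, dtype=float) + 273.15
    return r_ref * np.exp(e0 * (1.0 / (t_ref - t0) - 1.0 / (ts_k - t0)))


def generate_fluxes(
    met: pd.DataFrame, truth: TrueParameterTrajectory
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the NEE column from the forward model; return (records, truth_df).

    ``truth_df`` carries per-record true RE, GEP, noise-free NEE and the
    day's alpha/Pmax, aligned on the same index.
    """
    n = len(met)
    days = n // RECORDS_PER_DAY
    if len(truth.alpha_daily) != days:
        raise ValueError(
            f"truth covers {len(truth.alpha_daily)} days but met spans {days}"
        )
    day_ordinal = np.arange(n) // RECORDS_PER_DAY
    alpha = truth.alpha_daily[day_ordinal]
    pmax = truth.pmax_daily[day_ordinal]
    re_true = lloyd_taylor_re(met["ts"].to_numpy(), truth.r_ref, truth.e0)
    par = met["par"].to_numpy()
    # no photosynthesis below the night PAR threshold: keeps "RE = NEE at
    # night" exact under the same day/night convention the pipeline uses
    gep_true = np.where(
        par < NIGHT_PAR_THRESHOLD, 0.0, light_response(par, alpha, pmax)
    )
    nee_true = re_true - gep_true
    rng = np.random.default_rng(truth.seed)
    eps = (
        rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else np.zeros(n)
    )
    records = met.copy()
    records["nee"] = nee_true + eps
    truth_df = pd.DataFrame(
        {
            "re_true": re_true,
            "gep_true": gep_true,
            "nee_true": nee_true,
            "alpha_true": alpha,
            "pmax_true": pmax,
        },
        index=met.index,
    )
    return records, truth_df


def inject_gaps_and_low_ustar(
    records: pd.DataFrame, truth: TrueParameterTrajectory
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Punch gaps and create low-turbulence night episodes.

    Gap windows from ``truth.gap_spec`` are set to missing (``qc=missing``
    for NEE gaps).  A Bernoulli(``low_ustar_fraction``) draw over nighttime
    records assigns u* below 0.2 m s-1 and halves NEE there, mimicking the
    nighttime flux underestimation that the u* filter must remove.  Returns
    the modified records and a boolean truth mask with one ``gap_<var>``
    column per gapped variable and a ``low_ustar`` column.
    """
    out = records.copy()
    n = len(out)
    mask = pd.DataFrame(index=out.index)

    claimed: dict[str, np.ndarray] = {}
    for variable, start, length in truth.gap_spec:
        if variable not in DATA_COLUMNS:
            raise ValueError(f"unknown variable {variable!r} in gap_spec")
        if start < 0 or length < 1 or start + length > n:
            raise ValueError(f"gap ({variable}, {start}, {length}) out of range")
        taken = claimed.setdefault(variable, np.zeros(n, dtype=bool))
        sl = slice(start, start + length)
        if taken[sl].any():
            raise ValueError(f"overlapping gap specs for {variable!r}")
        taken[sl] = True

    for variable, taken in claimed.items():
        col = f"gap_{variable}"
        mask[col] = taken
        out.loc[taken, variable] = np.nan
        if variable == "nee":
            out.loc[taken, "qc"] = QC_MISSING

    rng = np.random.default_rng(truth.seed + 1)
    low = np.zeros(n, dtype=bool)
    if truth.low_ustar_fraction > 0:
        night = is_night(out).to_numpy() & out["nee"].notna().to_numpy()
        draw = rng.random(n) < truth.low_ustar_fraction
        low = night & draw
        out.loc[low, "ustar"] = rng.uniform(0.05, 0.19, size=int(low.sum()))
        out.loc[low, "nee"] = out.loc[low, "nee"] * 0.5
    mask["low_ustar"] = low
    return out, mask


def seasonal_trajectory(
    days: int,
    start: str | pd.Timestamp = "2011-01-01",
    on_years: set[int] | None = None,
    **kwargs,
) -> TrueParameterTrajectory:
    """Smooth seasonal alpha/Pmax trajectories over the simulated days.

    Pmax follows the stand's published photosynthetic phenology: a seasonal
    base of ~0.30 (winter) to ~0.70 mg m-2 s-1 (summer), a bimodal on-year
    pattern with peaks during fast culm growth (April) and late on-year
    leaf spreading (June), and a single off-year peak of ~0.9 during leaf
    spreading on the established culms (mid-May-July), so the off-year LS
    period carries the strongest uptake.  alpha varies between ~0.0020 and
    ~0.0033 mg umol-1 in antiphase with Pmax, matching the observed
    negative alpha-Pmax association.
    """
    on_years = on_years or set()
    dates = pd.date_range(pd.Timestamp(start).normalize(), periods=days, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    w = _season_weight(doy)
    pmax = 0.30 + 0.40 * w
    in_on_year = np.isin(dates.year.to_numpy(), list(on_years))

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((doy - center) / width) ** 2)

    # on-years: fast-growth peak (~mid April) + late leaf-spreading peak
    pmax = pmax + np.where(in_on_year, 0.20 * bump(105, 14) + 0.18 * bump(170, 16), 0.0)
    # off-years: single leaf-spreading peak on the renewed canopy (~mid June)
    pmax = pmax + np.where(~in_on_year, 0.32 * bump(168, 30), 0.0)
    alpha = 0.0034 - 0.0010 * w
    return TrueParameterTrajectory(alpha_daily=alpha, pmax_daily=pmax, **kwargs)


def synthetic_lai(
    days: int,
    seed: int = 0,
    start: str | pd.Timestamp = "2011-01-01",
    on_years: set[int] | None = None,
) -> pd.Series:
    """Daily leaf area index: seasonal 3-5.5 m2 m-2, lower mean in on-years."""
    on_years = on_years or set()
    dates = pd.date_range(pd.Timestamp(start).normalize(), periods=days, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    w = _season_weight(doy)
    base = 3.2 + 2.0 * w
    base = base - np.where(np.isin(dates.year.to_numpy(), list(on_years)), 0.35, 0.0)
    rng = np.random.default_rng(seed + 17)
    lai = np.clip(base + _ar1(rng, days, 0.9, 0.08), 0.5, None)
    return pd.Series(lai, index=dates, name="lai")


def generate_dataset(
    days: int,
    seed: int,
    truth: TrueParameterTrajectory | None = None,
    climate: ClimateConfig | None = None,
    start: str | pd.Timestamp = "2011-01-01",
    on_years: set[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Meteorology + fluxes + injected artifacts in one call.

    Returns ``(records, truth_df, mask)``.  When ``truth`` is omitted a
    seasonal trajectory with the run's seed is used.
    """
    if truth is None:
        truth = seasonal_trajectory(days, start=start, on_years=on_years, seed=seed)
    else:
        truth = replace(truth)
    met = generate_meteorology(days, seed, climate=climate, start=start)
    records, truth_df = generate_fluxes(met, truth)
    records, mask = inject_gaps_and_low_ustar(records, truth)
    return records, truth_df, mask
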