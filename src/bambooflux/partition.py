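"""Flux partitioning, model gap filling and aggregation.

Nighttime NEE equals ecosystem respiration (no photosynthesis in the dark),
so the Lloyd-Taylor model

    RE(Ts) = R_ref * exp( E0 * ( 1/(T_ref - T0) - 1/(Ts_K - T0) ) )

is fitted to u*-accepted nighttime NEE against soil temperature
(T_ref = 283.15 K, T0 = 227.13 K, the standard constants of the original
formulation).  NEE gaps are then model-filled — nighttime from Lloyd-Taylor,
daytime from the covering 5-day light-response fit — the series is
partitioned into RE (nighttime: measured NEE; daytime: Lloyd-Taylor) and
GEP = RE - NEE, and half-hourly fluxes are accumulated to daily, 5-day and
annual sums in gC m-2 (mass conversion 12/44 applied at aggregation only).
The sign convention is ecosystem-centric: negative NEE is a carbon sink.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lightresponse import LightResponseFit, year_windows
from .records import (
    HALF_HOUR_SECONDS,
    QC_MODEL,
    QC_OBSERVED,
    RECORDS_PER_DAY,
    is_night,
)
from .synthetic import lloyd_taylor_re

__all__ = [
    "LloydTaylorFit",
    "fit_lloyd_taylor",
    "fill_nee",
    "derive_re_gep",
    "aggregate",
    "MG_CO2_TO_GC",
]

T_REF = 283.15  # K: reference temperature (10 deg C)
T0 = 227.13  # K: lower temperature bound
MIN_NIGHT_OBS = 10

#: mg CO2 m-2 s-1 over one half hour -> gC m-2
MG_CO2_TO_GC = HALF_HOUR_SECONDS * (12.0 / 44.0) / 1000.0

_LT_LOWER = np.array([1e-8, 1e-8])
_LT_UPPER = np.array([10.0, 1000.0])
_LT_STARTS = (np.array([0.1, 308.56]), np.array([0.5, 100.0]), np.array([1.0, 500.0]))


@dataclass
class LloydTaylorFit:
    """Nighttime respiration model parameters for one fit window."""

    r_ref: float
    e0: float
    n_obs: int
    rmse: float
    converged: bool
    t_ref: float = T_REF
    t0: float = T0
    message: str = ""

    def predict(self, ts_c) -> np.ndarray:
        """RE (mg CO2 m-2 s-1) at soil temperature ``ts_c`` in deg C."""
        return lloyd_taylor_re(ts_c, self.r_ref, self.e0, self.t_ref, self.t0)


def fit_lloyd_taylor(
    records: pd.DataFrame,
    window: tuple[dt.date, dt.date] | None = None,
    min_obs: int = MIN_NIGHT_OBS,
) -> LloydTaylorFit:
    """Nonlinear least squares of Lloyd-Taylor RE on nighttime NEE.

    Uses u*-accepted, observed nighttime NEE-Ts pairs inside ``window``
    (the whole series if omitted).  Under-sampled windows and degenerate
    designs (soil temperature essentially constant, leaving E0
    unidentifiable) come back flagged; callers fall back to the annual fit.
    Bounded trust-region fit with a three-point multi-start on failure.
    """
    sel = records
    if window is not None:
        sel = records.loc[str(window[0]) : str(window[1])]
    night = (
        is_night(sel)
        & sel["nee"].notna()
        & sel["ts"].notna()
        & (sel["qc"] == QC_OBSERVED)
    )
    ts = sel.loc[night, "ts"].to_numpy(dtype=float)
    nee = sel.loc[night, "nee"].to_numpy(dtype=float)
    n_obs = int(night.sum())
    if n_obs < min_obs:
        return LloydTaylorFit(
            np.nan, np.nan, n_obs, np.nan, False, message=f"only {n_obs} night samples"
        )
    if np.ptp(ts) < 1.0:
        return LloydTaylorFit(
            np.nan,
            np.nan,
            n_obs,
            np.nan,
            False,
            message="soil temperature range < 1 K; E0 unidentifiable",
        )

    def residuals(theta):
        return lloyd_taylor_re(ts, theta[0], theta[1]) - nee

    best = None
    for x0 in _LT_STARTS:
        sol = least_squares(
            residuals,
            x0,
            bounds=(_LT_LOWER, _LT_UPPER),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.cost < 1e-20:
            break
    if best is None:
        return LloydTaylorFit(
            np.nan, np.nan, n_obs, np.nan, False, message="optimizer did not converge"
        )
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return LloydTaylorFit(
        r_ref=float(best.x[0]),
        e0=float(best.x[1]),
        n_obs=n_obs,
        rmse=rmse,
        converged=True,
    )


def _covering_fit(
    date: dt.date, lr_fits: list[LightResponseFit]
) -> tuple[LightResponseFit | None, bool]:
    """The converged fit whose window covers ``date``, else the nearest one.

    Second element reports whether a fallback to a neighbouring window was
    needed (for the run log).
    """
    valid = [f for f in lr_fits if f.converged]
    if not valid:
        return None, False
    for f in valid:
        if f.window_start <= date <= f.window_end:
            return f, False
    nearest = min(
        valid,
        key=lambda f: min(
            abs((date - f.window_start).days), abs((date - f.window_end).days)
        ),
    )
    return nearest, True


def fill_nee(
    records: pd.DataFrame,
    lt: LloydTaylorFit,
    lr_fits: list[LightResponseFit],
) -> tuple[pd.DataFrame, dict]:
    """Model-fill every NEE gap so the series becomes gap-free.

    Nighttime gaps take the Lloyd-Taylor prediction at the record's soil
    temperature; daytime gaps take the covering 5-day light-response fit's
    hyperbola at the record's PAR.  Gaps whose window fit failed use the
    nearest converged window and are counted in the report.
    """
    if not lt.converged:
        raise ValueError("cannot fill from a non-converged Lloyd-Taylor fit")
    out = records.copy()
    night = is_night(out).to_numpy()
    missing = out["nee"].isna().to_numpy()
    report = {"night_filled": 0, "day_filled": 0, "nearest_window_fallbacks": 0}

    night_fill = missing & night
    out.loc[night_fill, "nee"] = lt.predict(out.loc[night_fill, "ts"].to_numpy())
    report["night_filled"] = int(night_fill.sum())

    day_fill = missing & ~night
    if day_fill.any():
        dates = out.index[day_fill].date
        pars = out.loc[day_fill, "par"].to_numpy(dtype=float)
        filled = np.empty(len(pars))
        for j, (d, p) in enumerate(zip(dates, pars)):
            fit, fallback = _covering_fit(d, lr_fits)
            if fit is None:
                raise ValueError("no converged light-response fit available")
            if fallback:
                report["nearest_window_fallbacks"] += 1
            filled[j] = fit.predict_nee(p)
        out.loc[day_fill, "nee"] = filled
        report["day_filled"] = int(day_fill.sum())

    out.loc[missing, "qc"] = QC_MODEL
    return out, report


def derive_re_gep(records: pd.DataFrame, lt: LloydTaylorFit) -> pd.DataFrame:
    """Partition a gap-free NEE series into RE and GEP columns.

    Nighttime RE is the NEE itself (respiration is all there is in the
    dark); daytime RE is the Lloyd-Taylor prediction.  GEP = RE - NEE
    everywhere, which is identically zero at night.
    """
    if records["nee"].isna().any():
        raise ValueError("NEE series must be gap-free; run fill_nee first")
    out = records.copy()
    night = is_night(out).to_numpy()
    re = np.where(
        night,
        out["nee"].to_numpy(dtype=float),
        lt.predict(out["ts"].to_numpy(dtype=float)),
    )
    out["re"] = re
    out["gep"] = out["re"] - out["nee"]
    return out


def aggregate(records: pd.DataFrame, level: str = "daily") -> pd.DataFrame:
    """Accumulate half-hourly fluxes to ``daily``, ``5day`` or ``annual`` sums.

    Each half-hourly value in mg CO2 m-2 s-1 contributes
    ``value * 1800 s * 12/44 / 1000`` gC m-2.  Partial first/last days are
    excluded.  Daily rows carry ``fill_fraction``, the share of half hours
    whose qc is not ``observed``; coarser levels average it.  5-day blocks
    follow the light-response windows (the 73rd absorbs the year-end
    remainder); ``annual`` sums calendar years.
    """
    flux_cols = [c for c in ("nee", "re", "gep") if c in records.columns]
    if not flux_cols:
        raise ValueError("no flux columns to aggregate")
    by_day = records.groupby(records.index.normalize())
    counts = by_day.size()
    full_days = counts.index[counts == RECORDS_PER_DAY]
    daily = by_day[flux_cols].sum().loc[full_days] * MG_CO2_TO_GC
    daily["fill_fraction"] = (
        by_day["qc"].apply(lambda q: float((q != QC_OBSERVED).mean())).loc[full_days]
    )
    daily.index = pd.DatetimeIndex(daily.index, name="date")
    if level == "daily":
        return daily
    if level == "annual":
        grouped = daily.groupby(daily.index.year)
        out = grouped[flux_cols].sum()
        out["fill_fraction"] = grouped["fill_fraction"].mean()
        out["n_days"] = grouped.size()
        out.index.name = "year"
        return out
    if level == "5day":
        rows = []
        for year in sorted(set(daily.index.year)):
            for k, (s, e) in enumerate(year_windows(year), start=1):
                block = daily.loc[str(s) : str(e)]
                if block.empty:
                    continue
                row = {"year": year, "window": k, "start": s, "end": e}
                for c in flux_cols:
                    row[c] = float(block[c].sum())
                row["fill_fraction"] = float(block["fill_fraction"].mean())
                row["n_days"] = len(block)
                rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown aggregation level {level!r}")
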