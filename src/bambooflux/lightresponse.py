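"""Windowed light-response parameter extraction.

Daytime NEE responds to photosynthetic radiation through the rectangular
hyperbola

    -NEE = alpha * PAR * Pmax / (alpha * PAR + Pmax) - RE

whose initial slope is the apparent quantum efficiency ``alpha``
(mg CO2 umol-1) and whose asymptote is the maximum photosynthetic rate
``Pmax`` (mg CO2 m-2 s-1); ``RE`` is the window's mean daytime respiration
offset.  Because a single day rarely holds enough daytime half hours for a
stable three-parameter fit, the model is fitted in non-overlapping 5-day
windows — 73 per calendar year, the last window absorbing the year-end
remainder — and the resulting alpha/Pmax series is optionally smoothed with
a Gaussian kernel to show the seasonal trend.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .records import QC_OBSERVED, is_night
from .synthetic import light_response

__all__ = [
    "LightResponseFit",
    "fit_window",
    "fit_year",
    "year_windows",
    "smooth_series",
    "fits_to_frame",
    "fits_from_frame",
]

WINDOW_DAYS = 5
WINDOWS_PER_YEAR = 73
MIN_WINDOW_OBS = 20

# alpha (mg umol-1), Pmax (mg m-2 s-1), RE (mg m-2 s-1)
LOWER_BOUNDS = np.array([1e-5, 0.01, 0.0])
UPPER_BOUNDS = np.array([0.05, 5.0, 2.0])
START_VALUES = np.array([0.002, 0.5, 0.1])


#: fits whose alpha or Pmax standard error exceeds this fraction of the
#: estimate are flagged: the window's radiation range did not constrain them
#: (typical of winter windows that never approach light saturation)
MAX_RELATIVE_SE = 0.5


@dataclass
class LightResponseFit:
    """Fitted light-response parameters for one 5-day window."""

    window_start: dt.date
    window_end: dt.date
    alpha: float
    pmax: float
    re: float
    n_obs: int
    converged: bool
    rmse: float = float("nan")
    alpha_se: float = float("nan")
    pmax_se: float = float("nan")
    re_se: float = float("nan")
    message: str = ""

    @property
    def alpha_ug(self) -> float:
        """alpha in ug umol-1 (reporting convention: 1000x the mg value)."""
        return self.alpha * 1000.0

    def predict_nee(self, par) -> np.ndarray:
        """NEE predicted by the fitted hyperbola at radiation ``par``."""
        return self.re - light_response(par, self.alpha, self.pmax)


def _failed(window, n_obs, message) -> LightResponseFit:
    return LightResponseFit(
        window_start=window[0],
        window_end=window[1],
        alpha=float("nan"),
        pmax=float("nan"),
        re=float("nan"),
        n_obs=n_obs,
        converged=False,
        message=message,
    )


def fit_window(
    records: pd.DataFrame,
    window: tuple[dt.date, dt.date],
    min_obs: int = MIN_WINDOW_OBS,
) -> LightResponseFit:
    """Fit the hyperbola to the daytime observed records of one window.

    Only records with ``qc=observed`` and PAR at or above the day threshold
    enter the fit.  Under-sampled windows, radiation designs with no spread
    (alpha and Pmax jointly unidentifiable) and non-converged or
    bound-pinned solutions come back flagged rather than raising.
    """
    start, end = window
    day = records.loc[str(start) : str(end)]
    sel = (
        (~is_night(day))
        & day["nee"].notna()
        & day["par"].notna()
        & (day["qc"] == QC_OBSERVED)
    )
    par = day.loc[sel, "par"].to_numpy(dtype=float)
    neg_nee = -day.loc[sel, "nee"].to_numpy(dtype=float)
    n_obs = int(sel.sum())
    if n_obs < min_obs:
        return _failed(window, n_obs, f"only {n_obs} daytime samples")
    if np.ptp(par) < 50.0:
        return _failed(window, n_obs, "no radiation spread; parameters unidentifiable")

    def residuals(theta):
        alpha, pmax, re = theta
        return light_response(par, alpha, pmax) - re - neg_nee

    sol = least_squares(
        residuals,
        START_VALUES,
        bounds=(LOWER_BOUNDS, UPPER_BOUNDS),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        return _failed(window, n_obs, sol.message)
    pinned = np.isclose(sol.x, LOWER_BOUNDS, rtol=0, atol=1e-9) | np.isclose(
        sol.x, UPPER_BOUNDS, rtol=1e-9
    )
    # RE pinned at its natural zero is physically fine; alpha/Pmax at a
    # bound means the hyperbola degenerated.
    converged = not (pinned[0] or pinned[1])
    message = "" if converged else "parameter pinned at bound"
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    # parameter standard errors from the Gauss-Newton covariance; a window
    # that never approaches saturation cannot constrain Pmax, and such
    # fits must not enter the seasonal series
    se = np.full(3, np.nan)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (
            np.sum(sol.fun**2) / (n_obs - 3)
        )
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        converged = False
        message = "singular Jacobian"
    if converged and (
        se[0] > MAX_RELATIVE_SE * sol.x[0] or se[1] > MAX_RELATIVE_SE * sol.x[1]
    ):
        converged = False
        message = "alpha/Pmax not constrained by the window's radiation range"
    return LightResponseFit(
        window_start=start,
        window_end=end,
        alpha=float(sol.x[0]),
        pmax=float(sol.x[1]),
        re=float(sol.x[2]),
        n_obs=n_obs,
        converged=converged,
        rmse=rmse,
        alpha_se=float(se[0]),
        pmax_se=float(se[1]),
        re_se=float(se[2]),
        message=message,
    )


def year_windows(year: int) -> list[tuple[dt.date, dt.date]]:
    """The 73 consecutive 5-day windows of a calendar year.

    Windows start on Jan 1; the 73rd absorbs the remainder, so it spans
    Dec 27-31 in common years and Dec 26-31 (6 days) in leap years.
    """
    first = dt.date(year, 1, 1)
    windows = []
    for k in range(WINDOWS_PER_YEAR - 1):
        s = first + dt.timedelta(days=WINDOW_DAYS * k)
        windows.append((s, s + dt.timedelta(days=WINDOW_DAYS - 1)))
    last_start = first + dt.timedelta(days=WINDOW_DAYS * (WINDOWS_PER_YEAR - 1))
    windows.append((last_start, dt.date(year, 12, 31)))
    return windows


def fit_year(
    records: pd.DataFrame, year: int | None = None, min_obs: int = MIN_WINDOW_OBS
) -> list[LightResponseFit]:
    """Fit all 73 windows of one calendar year (failed fits flagged)."""
    if year is None:
        year = int(records.index[0].year)
    return [fit_window(records, w, min_obs=min_obs) for w in year_windows(year)]


def fits_to_frame(fits: list[LightResponseFit]) -> pd.DataFrame:
    """Tabulate a fit sequence (alpha reported in ug umol-1 alongside mg)."""
    return pd.DataFrame(
        {
            "window_start": [f.window_start for f in fits],
            "window_end": [f.window_end for f in fits],
            "alpha": [f.alpha for f in fits],
            "alpha_ug": [f.alpha_ug for f in fits],
            "pmax": [f.pmax for f in fits],
            "re": [f.re for f in fits],
            "n_obs": [f.n_obs for f in fits],
            "converged": [f.converged for f in fits],
            "rmse": [f.rmse for f in fits],
        }
    )


def smooth_series(
    fits: list[LightResponseFit], sigma: float = 2.0
) -> pd.DataFrame:
    """Gaussian-smoothed alpha and Pmax trends over the window series.

    ``sigma`` is in units of windows (default 2 = 10 days).  Non-converged
    windows are excluded and the kernel renormalized over the remaining
    weight (normalized convolution), so a constant series is preserved
    exactly and gaps do not drag the trend toward zero.  Output length
    equals input length; windows with no kernel support stay NaN.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ok = np.array([f.converged for f in fits], dtype=float)
    if ok.sum() < 5:
        raise ValueError("need at least 5 converged fits to smooth")
    out = {}
    for name in ("alpha", "pmax"):
        v = np.array([getattr(f, name) for f in fits], dtype=float)
        v = np.where(ok > 0, v, 0.0)
        num = gaussian_filter1d(v * ok, sigma, mode="constant", cval=0.0)
        den = gaussian_filter1d(ok, sigma, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{name}_smooth"] = np.where(den > 1e-12, num / den, np.nan)
    return pd.DataFrame(out)


def fits_from_frame(frame: pd.DataFrame) -> list[LightResponseFit]:
    """Rebuild a fit sequence from a :func:`fits_to_frame` table."""
    fits = []
    for _, row in frame.iterrows():
        fits.append(
            LightResponseFit(
                window_start=pd.Timestamp(row["window_start"]).date(),
                window_end=pd.Timestamp(row["window_end"]).date(),
                alpha=float(row["alpha"]),
                pmax=float(row["pmax"]),
                re=float(row["re"]),
                n_obs=int(row["n_obs"]),
                converged=bool(row["converged"]),
                rmse=float(row["rmse"]),
            )
        )
    return fits
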