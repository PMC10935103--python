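"""Quality control and meteorological gap filling.

Two corrections are applied to a half-hourly tower series before flux
partitioning:

* **u\\* filtering** — nighttime records with friction velocity below a
  rejection threshold (default 0.2 m s-1) are discarded, because weak
  turbulence lets respired CO2 pool below the canopy and biases nighttime
  NEE low.
* **meteorological gap filling** — gaps of at most 2 h (4 half-hour records)
  are linearly interpolated between their flanking observations; longer gaps
  use the mean-diurnal-variation (MDV) estimate: for each missing slot, the
  mean of observed values at the same time of day within +/- a window of
  days (default 7).

NEE gaps are *not* filled here; they are model-filled during partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    DATA_COLUMNS,
    QC_LINEAR,
    QC_MDV,
    QC_MISSING,
    QC_OBSERVED,
    QC_REJECTED,
    RECORDS_PER_DAY,
    is_night,
)

__all__ = ["GapSegment", "apply_ustar_filter", "find_gaps", "fill_meteo"]

DEFAULT_USTAR_THRESHOLD = 0.2
MAX_LINEAR_GAP = 4  # records; 2 h at a 30-min cadence
DEFAULT_MDV_WINDOW_DAYS = 7


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of missing values in one variable."""

    variable: str
    start_index: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("gap length must be >= 1")


def apply_ustar_filter(
    records: pd.DataFrame, threshold: float = DEFAULT_USTAR_THRESHOLD
) -> tuple[pd.DataFrame, int]:
    """Reject low-turbulence nighttime NEE.

    Nighttime records (PAR < 5 umol m-2 s-1) with ``ustar < threshold`` have
    NEE set to missing and ``qc=rejected``; daytime records are untouched.
    Returns the filtered copy and the rejection count.
    """
    if threshold < 0:
        raise ValueError("u* threshold must be non-negative")
    out = records.copy()
    reject = (
        is_night(out) & (out["ustar"] < threshold) & out["nee"].notna()
    ).to_numpy()
    out.loc[reject, "nee"] = np.nan
    out.loc[reject, "qc"] = QC_REJECTED
    return out, int(reject.sum())


def find_gaps(records: pd.DataFrame, variable: str) -> list[GapSegment]:
    """Maximal runs of missing values in ``variable``, in index order."""
    if variable not in records.columns or variable not in DATA_COLUMNS:
        raise ValueError(f"unknown variable {variable!r}")
    missing = records[variable].isna().to_numpy()
    if not missing.any():
        return []
    edges = np.diff(missing.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if missing[0]:
        starts = np.r_[0, starts]
    if missing[-1]:
        ends = np.r_[ends, len(missing)]
    return [
        GapSegment(variable, int(s), int(e - s)) for s, e in zip(starts, ends)
    ]


def fill_meteo(
    records: pd.DataFrame,
    variable: str,
    mdv_window_days: int = DEFAULT_MDV_WINDOW_DAYS,
    max_linear_gap: int = MAX_LINEAR_GAP,
) -> tuple[pd.DataFrame, dict]:
    """Fill gaps in one meteorological variable.

    Gaps of at most ``max_linear_gap`` records with observations on both
    sides are linearly interpolated; all other gaps use the MDV estimate
    computed from *originally observed* values only (so filling is
    idempotent and order-independent).  Slots whose MDV window holds no
    observation stay missing and are reported.

    Provenance lands in a ``qc_<variable>`` column; the fill report gives
    counts per method plus the indices of MDV failures.
    """
    if variable == "nee":
        raise ValueError("NEE is model-filled during partitioning, not here")
    out = records.copy()
    qc_col = f"qc_{variable}"
    if qc_col not in out.columns:
        out[qc_col] = np.where(out[variable].isna(), QC_MISSING, QC_OBSERVED)

    values = out[variable].to_numpy(dtype=float)
    observed_mask = out[qc_col].to_numpy() == QC_OBSERVED
    observed_values = np.where(observed_mask, values, np.nan)
    gaps = find_gaps(out, variable)
    n = len(out)
    report = {
        "variable": variable,
        "n_gaps": len(gaps),
        "linear": 0,
        "mdv": 0,
        "unfilled": 0,
        "unfilled_indices": [],
    }
    slot = (
        out.index.hour.to_numpy() * 2 + out.index.minute.to_numpy() // 30
    )

    for gap in gaps:
        lo, hi = gap.start_index, gap.start_index + gap.length
        has_flanks = (
            lo > 0
            and hi < n
            and np.isfinite(observed_values[lo - 1])
            and np.isfinite(observed_values[hi])
        )
        if gap.length <= max_linear_gap and has_flanks:
            x = np.arange(lo, hi, dtype=float)
            filled = np.interp(
                x,
                [lo - 1.0, float(hi)],
                [observed_values[lo - 1], observed_values[hi]],
            )
            values[lo:hi] = filled
            out.iloc[lo:hi, out.columns.get_loc(qc_col)] = QC_LINEAR
            report["linear"] += gap.length
            continue
        for i in range(lo, hi):
            window_lo = max(0, i - mdv_window_days * RECORDS_PER_DAY)
            window_hi = min(n, i + mdv_window_days * RECORDS_PER_DAY + 1)
            sel = observed_values[window_lo:window_hi]
            same_slot = slot[window_lo:window_hi] == slot[i]
            candidates = sel[same_slot & np.isfinite(sel)]
            if candidates.size:
                values[i] = candidates.mean()
                out.iloc[i, out.columns.get_loc(qc_col)] = QC_MDV
                report["mdv"] += 1
            else:
                report["unfilled"] += 1
                report["unfilled_indices"].append(i)

    out[variable] = values
    return out, report
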