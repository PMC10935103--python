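"""Half-hourly tower record conventions.

A tower dataset is a :class:`pandas.DataFrame` with a ``DatetimeIndex`` named
``timestamp`` at a strict 30-minute cadence and the columns

======== =====================================================================
column   meaning (units)
======== =====================================================================
nee      net ecosystem exchange, mg CO2 m-2 s-1; negative = uptake (sink)
par      photosynthetically active radiation, umol m-2 s-1
ta       air temperature, deg C
ts       soil temperature (5 cm), deg C
vpd      vapor pressure deficit, hPa
prec     precipitation, mm per 30 min
ustar    friction velocity, m s-1
qc       flux QC flag, one of :data:`QC_FLAGS`
======== =====================================================================

The ``qc`` column tracks the state of the NEE flux series.  Meteorological
gap filling records its provenance in per-variable ``qc_<name>`` columns
created on demand by :func:`bambooflux.qc.fill_meteo`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QC_OBSERVED = "observed"
QC_REJECTED = "rejected"
QC_LINEAR = "gapfilled_linear"
QC_MDV = "gapfilled_mdv"
QC_MODEL = "gapfilled_model"
QC_MISSING = "missing"

QC_FLAGS = frozenset(
    {QC_OBSERVED, QC_REJECTED, QC_LINEAR, QC_MDV, QC_MODEL, QC_MISSING}
)

#: PAR below which a half hour counts as night (umol m-2 s-1).
NIGHT_PAR_THRESHOLD = 5.0

MET_COLUMNS = ("par", "ta", "ts", "vpd", "prec", "ustar")
DATA_COLUMNS = ("nee",) + MET_COLUMNS

HALF_HOUR_SECONDS = 1800
RECORDS_PER_DAY = 48


def is_night(records: pd.DataFrame) -> pd.Series:
    """Boolean night mask: PAR below :data:`NIGHT_PAR_THRESHOLD`."""
    return records["par"] < NIGHT_PAR_THRESHOLD


def validate_records(records: pd.DataFrame) -> None:
    """Check structural invariants of a half-hourly dataset.

    Raises ``ValueError`` on: non-monotonic or non-30-min timestamps,
    negative PAR/precipitation/u*, or an unknown qc flag.
    """
    idx = records.index
    if len(idx) > 1:
        steps = np.diff(idx.values).astype("timedelta64[s]").astype(int)
        if not np.all(steps == HALF_HOUR_SECONDS):
            raise ValueError("timestamps must increase in strict 30-min steps")
    for col in ("par", "prec", "ustar"):
        if col in records and (records[col].dropna() < 0).any():
            raise ValueError(f"{col} must be non-negative")
    if "qc" in records:
        bad = set(records["qc"].dropna().unique()) - QC_FLAGS
        if bad:
            raise ValueError(f"unknown qc flags: {sorted(bad)}")


def half_hourly_index(start: str | pd.Timestamp, days: int) -> pd.DatetimeIndex:
    """A complete 30-min index covering ``days`` days from midnight of ``start``."""
    if days < 1:
        raise ValueError("days must be >= 1")
    start = pd.Timestamp(start).normalize()
    return pd.date_range(
        start, periods=days * RECORDS_PER_DAY, freq="30min", name="timestamp"
    )
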