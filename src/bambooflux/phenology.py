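"""Phenology-period segmentation and stratified statistics.

Moso bamboo stands alternate between on-years (mass shoot production,
"explosive" culm growth) and off-years (few shoots, leaf renewal on the
established culms).  The full phenology cycle is divided into six periods:

* ``FG_ON``  — fast growth of new culms (on-years)
* ``LS_ON``  — leaf spreading on the new culms (on-years)
* ``LR_OFF`` — leaf renewal: old leaves shed, new ones flushed (off-years)
* ``LS_OFF`` — leaf spreading on the established culms (off-years)
* ``NF_ON`` / ``NF_OFF`` — the remaining "normal" days of each year class

A calendar lists the dated FG/LS/LR intervals per year and each year's
on/off class; every other day falls into the NF period of its year class,
so labeling is a partition of the year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhenologyCalendar", "PERIOD_LABELS", "period_stats", "label_blocks"]

PERIOD_LABELS = ("FG_ON", "LS_ON", "NF_ON", "LR_OFF", "LS_OFF", "NF_OFF")
_ON_LABELS = {"FG_ON", "LS_ON", "NF_ON"}
_OFF_LABELS = {"LR_OFF", "LS_OFF", "NF_OFF"}
#: tie-break order for majority labeling of blocks (earlier period wins)
_PERIOD_ORDER = {label: i for i, label in enumerate(PERIOD_LABELS)}


@dataclass
class PhenologyCalendar:
    """Dated six-period segmentation with on/off-year classes.

    ``periods`` holds the explicitly dated intervals (inclusive);
    NF periods are implicit remainders.  ``year_class`` maps each covered
    year to ``"on"`` or ``"off"``.
    """

    periods: list[tuple[dt.date, dt.date, str]] = field(default_factory=list)
    year_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[int, list[tuple[dt.date, dt.date]]] = {}
        for start, end, label in self.periods:
            if label not in PERIOD_LABELS:
                raise ValueError(f"unknown period label {label!r}")
            if label in ("NF_ON", "NF_OFF"):
                raise ValueError("NF periods are implicit; do not date them")
            if end < start:
                raise ValueError(f"period {label} ends before it starts")
            year = start.year
            if end.year != year:
                raise ValueError("periods may not span calendar years")
            cls = self.year_class.get(year)
            if cls is None:
                raise ValueError(f"year {year} missing from year_class")
            if cls not in ("on", "off"):
                raise ValueError(f"year class must be 'on' or 'off', got {cls!r}")
            if (cls == "on") != (label in _ON_LABELS):
                raise ValueError(
                    f"label {label} inconsistent with {year} being an {cls}-year"
                )
            for s, e in seen.get(year, []):
                if start <= e and s <= end:
                    raise ValueError(f"overlapping periods in {year}")
            seen.setdefault(year, []).append((start, end))

    def label_days(self, dates) -> pd.Series:
        """Period label for every date (NF fills the remainder)."""
        dates = pd.DatetimeIndex(dates)
        years = dates.year.to_numpy()
        missing = set(years) - set(self.year_class)
        if missing:
            raise ValueError(f"years absent from calendar: {sorted(missing)}")
        labels = np.array(
            [
                "NF_ON" if self.year_class[y] == "on" else "NF_OFF"
                for y in years
            ],
            dtype=object,
        )
        d = dates.normalize()
        for start, end, label in self.periods:
            inside = (d >= pd.Timestamp(start)) & (d <= pd.Timestamp(end))
            labels[np.asarray(inside)] = label
        return pd.Series(labels, index=dates, name="period")

    def to_csv(self, path: str | Path) -> None:
        """Write the two-section delimited text format (periods + classes)."""
        lines = ["year,label,start,end"]
        for start, end, label in sorted(self.periods):
            lines.append(f"{start.year},{label},{start.isoformat()},{end.isoformat()}")
        lines.append("year,class")
        for year in sorted(self.year_class):
            lines.append(f"{year},{self.year_class[year]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenologyCalendar":
        periods: list[tuple[dt.date, dt.date, str]] = []
        year_class: dict[int, str] = {}
        section = None
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line == "year,label,start,end":
                section = "periods"
                continue
            if line == "year,class":
                section = "classes"
                continue
            parts = line.split(",")
            if section == "periods":
                _, label, start, end = parts
                periods.append(
                    (dt.date.fromisoformat(start), dt.date.fromisoformat(end), label)
                )
            elif section == "classes":
                year_class[int(parts[0])] = parts[1]
            else:
                raise ValueError(f"calendar file has no section header before: {raw!r}")
        return cls(periods=periods, year_class=year_class)

    @classmethod
    def synthetic(cls, year_class: dict[int, str]) -> "PhenologyCalendar":
        """A plausible subtropical calendar for simulated years.

        On-years: fast growth through April, leaf spreading May-June.
        Off-years: leaf renewal April to mid-May, leaf spreading
        mid-May-July.
        """
        periods = []
        for year, c in year_class.items():
            if c == "on":
                periods.append((dt.date(year, 4, 1), dt.date(year, 4, 30), "FG_ON"))
                periods.append((dt.date(year, 5, 1), dt.date(year, 6, 30), "LS_ON"))
            else:
                periods.append((dt.date(year, 4, 1), dt.date(year, 5, 15), "LR_OFF"))
                periods.append((dt.date(year, 5, 16), dt.date(year, 7, 31), "LS_OFF"))
        return cls(periods=periods, year_class=dict(year_class))


def label_blocks(block_table: pd.DataFrame, calendar: PhenologyCalendar) -> pd.Series:
    """Majority-day period label for each 5-day block row.

    Expects ``start``/``end`` date columns (as produced by
    ``partition.aggregate(..., "5day")``).  Ties break toward the earlier
    period in the cycle order FG -> LS -> NF (LR -> LS -> NF in off-years).
    """
    labels = []
    for _, row in block_table.iterrows():
        days = pd.date_range(row["start"], row["end"], freq="D")
        day_labels = calendar.label_days(days)
        counts = day_labels.value_counts()
        top = counts.max()
        tied = sorted(
            (label for label, c in counts.items() if c == top),
            key=lambda label: _PERIOD_ORDER[label],
        )
        labels.append(tied[0])
    return pd.Series(labels, index=block_table.index, name="period")


def period_stats(values: pd.DataFrame, label_col: str = "period") -> pd.DataFrame:
    """Mean +/- sd per (period, variable) over a labeled block table.

    Every numeric column is summarized within each period stratum; rows
    with a missing value (e.g. a failed window fit) are dropped for that
    variable only.  The sd is the population sd (ddof=0), so a
    single-block stratum reports sd = 0.  Empty strata appear with n = 0
    and no mean.
    """
    numeric = values.select_dtypes(include=[np.number]).columns
    rows = []
    present = [l for l in PERIOD_LABELS if l in set(values[label_col])]
    for label in present:
        stratum = values[values[label_col] == label]
        for var in numeric:
            x = stratum[var].dropna().to_numpy(dtype=float)
            if x.size == 0:
                rows.append(
                    {"period": label, "variable": var, "mean": np.nan,
                     "sd": np.nan, "n": 0}
                )
            else:
                rows.append(
                    {
                        "period": label,
                        "variable": var,
                        "mean": float(x.mean()),
                        "sd": float(x.std(ddof=0)),
                        "n": int(x.size),
                    }
                )
    return pd.DataFrame(rows)
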