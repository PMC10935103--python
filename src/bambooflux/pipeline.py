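"""End-to-end orchestration: simulate -> qc -> partition -> analyze.

``run_pipeline`` chains the stages in order (u* filter and meteorological
gap filling; per-year Lloyd-Taylor fit, 5-day light-response fits and model
filling of NEE; RE/GEP partitioning; daily/5-day/annual aggregation;
phenology-period statistics; correlation and path analysis) and writes every
result as delimited text together with a run log and a manifest carrying the
config hash.  Identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, qc
from .drivers import fit_path_model, indirect_effects, pearson_matrix
from .lightresponse import fit_year, fits_to_frame, smooth_series
from .partition import aggregate, derive_re_gep, fill_nee, fit_lloyd_taylor
from .phenology import PhenologyCalendar, label_blocks, period_stats
from .records import MET_COLUMNS
from .synthetic import generate_dataset, synthetic_lai

__all__ = ["PipelineConfig", "simulate_command", "run_pipeline", "assemble_driver_table"]


@dataclass
class PipelineConfig:
    """Run configuration with the station defaults."""

    data_path: str = "data.csv"
    lai_path: str = "lai.csv"
    calendar_path: str = "calendar.csv"
    ustar_threshold: float = 0.2
    mdv_window_days: int = 7
    window_length_days: int = 5
    gaussian_sigma_windows: float = 2.0
    lloyd_taylor_scope: str = "annual"  # "annual" (per calendar year) or "global"
    min_window_obs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ustar_threshold < 0:
            raise ValueError("ustar_threshold must be non-negative")
        if self.mdv_window_days < 1 or self.window_length_days < 1:
            raise ValueError("window settings must be positive")
        if self.gaussian_sigma_windows <= 0:
            raise ValueError("gaussian_sigma_windows must be positive")
        if self.lloyd_taylor_scope not in ("annual", "global"):
            raise ValueError("lloyd_taylor_scope must be 'annual' or 'global'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**io.load_config(path))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_command(
    outdir: str | Path,
    years: int = 2,
    seed: int = 0,
    start_year: int = 2011,
    noise_sd: float = 0.05,
    low_ustar_fraction: float = 0.1,
    n_random_gaps: int = 40,
) -> dict[str, Path]:
    """Write a synthetic dataset bundle consumable by :func:`run_pipeline`.

    Odd calendar years are on-years (mass shooting), even ones off-years.
    Random NEE and meteorology gaps of mixed lengths (1 record to 3 days)
    plus low-u* nighttime episodes are injected, and the generating truth is
    written alongside for oracle use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    year_class = {
        start_year + k: ("on" if (start_year + k) % 2 == 1 else "off")
        for k in range(years)
    }
    days = sum(
        pd.Timestamp(f"{y}-12-31").dayofyear for y in year_class
    )
    on_years = {y for y, c in year_class.items() if c == "on"}

    gap_rng = np.random.default_rng(seed + 101)
    n_records = days * 48
    gap_spec: list[tuple[str, int, int]] = []
    taken: dict[str, set[int]] = {}
    gap_vars = ["nee"] * (n_random_gaps // 2) + list(
        gap_rng.choice(MET_COLUMNS[:-1], size=n_random_gaps - n_random_gaps // 2)
    )
    for var in gap_vars:
        length = int(gap_rng.choice([1, 2, 4, 8, 48, 144]))
        start = int(gap_rng.integers(48, n_records - 200))
        cells = set(range(start, start + length))
        if cells & taken.setdefault(var, set()):
            continue  # skip rather than overlap
        taken[var] |= cells
        gap_spec.append((var, start, length))

    from .synthetic import seasonal_trajectory

    truth = seasonal_trajectory(
        days,
        start=f"{start_year}-01-01",
        on_years=on_years,
        noise_sd=noise_sd,
        gap_spec=gap_spec,
        low_ustar_fraction=low_ustar_fraction,
        seed=seed,
    )
    records, truth_df, mask = generate_dataset(
        days, seed, truth=truth, start=f"{start_year}-01-01", on_years=on_years
    )
    lai = synthetic_lai(days, seed=seed, start=f"{start_year}-01-01", on_years=on_years)
    calendar = PhenologyCalendar.synthetic(year_class)

    paths = {
        "data": outdir / "data.csv",
        "truth": outdir / "truth.csv",
        "mask": outdir / "mask.csv",
        "lai": outdir / "lai.csv",
        "calendar": outdir / "calendar.csv",
    }
    io.write_half_hourly(records, paths["data"])
    io.write_half_hourly(truth_df, paths["truth"])
    io.write_half_hourly(mask, paths["mask"])
    io.write_lai(lai, paths["lai"])
    calendar.to_csv(paths["calendar"])
    return paths


def assemble_driver_table(
    records: pd.DataFrame,
    five_day: pd.DataFrame,
    window_fits: pd.DataFrame,
    lai: pd.Series,
    calendar: PhenologyCalendar,
) -> pd.DataFrame:
    """The aligned 5-day analysis table: factors, fluxes, parameters, labels."""
    rows = []
    lai_daily = lai.copy()
    lai_daily.index = pd.DatetimeIndex(lai_daily.index).normalize()
    for _, blk in five_day.iterrows():
        sl = records.loc[str(blk["start"]) : str(blk["end"])]
        row = {
            "year": int(blk["year"]),
            "window": int(blk["window"]),
            "start": blk["start"],
            "end": blk["end"],
            "nee": blk["nee"],
            "re": blk["re"],
            "gep": blk["gep"],
            "vpd": float(sl["vpd"].mean()),
            "prec": float(sl["prec"].sum()),
            "par": float(sl["par"].mean()),
            "ta": float(sl["ta"].mean()),
            "ts": float(sl["ts"].mean()),
            "lai": float(lai_daily.loc[str(blk["start"]) : str(blk["end"])].mean()),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    fits = window_fits.copy()
    fits["year"] = pd.to_datetime(fits["window_start"]).dt.year
    fits["window"] = fits.groupby("year").cumcount() + 1
    fits.loc[~fits["converged"], ["alpha", "pmax"]] = np.nan
    table = table.merge(
        fits[["year", "window", "alpha", "pmax"]], on=["year", "window"], how="left"
    )
    table["alpha"] = table["alpha"] * 1000.0  # report in ug umol-1
    table["period"] = label_blocks(table, calendar).to_numpy()
    table["year_class"] = [calendar.year_class[y] for y in table["year"]]
    return table


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the result bundle to ``outdir``.

    Returns a summary dict (paths, log counts).  On any stage failure the
    partially written outputs are removed and the error re-raised with a
    stage tag.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: list[str] = [f"config_hash {config.config_hash()}"]

    def emit(name: str, table: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        io.write_table(table, path, index=index)
        written.append(path)
        return path

    stage = "load"
    try:
        records = io.read_half_hourly(config.data_path)
        lai = io.read_lai(config.lai_path)
        calendar = PhenologyCalendar.from_csv(config.calendar_path)

        stage = "qc"
        records, n_rejected = qc.apply_ustar_filter(records, config.ustar_threshold)
        log.append(f"qc: rejected {n_rejected} low-u* night records")
        for var in MET_COLUMNS:
            records, report = qc.fill_meteo(
                records, var, mdv_window_days=config.mdv_window_days
            )
            log.append(
                "qc: {variable} gaps={n_gaps} linear={linear} mdv={mdv} "
                "unfilled={unfilled}".format(**report)
            )

        stage = "partition"
        years = sorted(set(records.index.year))
        global_lt = fit_lloyd_taylor(records)
        filled_years, re_gep_years, all_fits, lt_rows = [], [], [], []
        for year in years:
            yr = records.loc[str(year)]
            lt = (
                fit_lloyd_taylor(yr)
                if config.lloyd_taylor_scope == "annual"
                else global_lt
            )
            if not lt.converged:
                log.append(f"partition: {year} Lloyd-Taylor fallback to global fit")
                lt = global_lt
            if not lt.converged:
                raise ValueError("no converged Lloyd-Taylor fit available")
            lt_rows.append(
                {"year": year, "r_ref": lt.r_ref, "e0": lt.e0,
                 "n_obs": lt.n_obs, "rmse": lt.rmse}
            )
            fits = fit_year(yr, year, min_obs=config.min_window_obs)
            n_failed = sum(not f.converged for f in fits)
            log.append(f"lightresponse: {year} windows=73 failed={n_failed}")
            filled, fill_report = fill_nee(yr, lt, fits)
            log.append(
                "partition: {year} night_filled={night_filled} "
                "day_filled={day_filled} fallbacks={nearest_window_fallbacks}".format(
                    year=year, **fill_report
                )
            )
            filled_years.append(filled)
            re_gep_years.append(derive_re_gep(filled, lt))
            all_fits.extend(fits)
        flux_records = pd.concat(re_gep_years)
        window_table = fits_to_frame(all_fits)
        smooth = smooth_series(all_fits, sigma=config.gaussian_sigma_windows)
        window_table = pd.concat([window_table, smooth], axis=1)

        stage = "aggregate"
        daily = aggregate(flux_records, "daily")
        five_day = aggregate(flux_records, "5day")
        annual = aggregate(flux_records, "annual")

        stage = "phenology"
        driver_table = assemble_driver_table(
            flux_records, five_day, window_table, lai, calendar
        )
        stats = period_stats(
            driver_table[["period", "nee", "re", "gep", "pmax", "alpha"]]
        )

        stage = "drivers"
        correlations = pd.concat(
            [
                pearson_matrix(driver_table, driver_table["period"]),
                pearson_matrix(driver_table, driver_table["year_class"]),
                pearson_matrix(driver_table),
            ],
            ignore_index=True,
        )
        path_rows, indirect_rows = [], []
        strata = [("period", s) for s in driver_table["period"].unique()]
        strata += [("year_class", s) for s in driver_table["year_class"].unique()]
        strata += [("all", "all")]
        for kind, name in strata:
            labels = (
                pd.Series("all", index=driver_table.index)
                if kind == "all"
                else driver_table[kind]
            )
            try:
                result = fit_path_model(driver_table, name, strata=labels)
            except ValueError as err:
                log.append(f"drivers: path model skipped for {name}: {err}")
                continue
            for (parent, child), pc in result.direct.items():
                path_rows.append(
                    {"stratum": name, "arrow": f"{parent}->{child}", "pc": pc,
                     "n": result.n}
                )
            indirect_rows.append(indirect_effects(result))
            for flag in result.flags:
                log.append(f"drivers: {name}: {flag}")

        stage = "write"
        emit("daily_fluxes.csv", daily, index=True)
        emit("five_day_fluxes.csv", five_day)
        emit("annual_fluxes.csv", annual, index=True)
        emit("window_fits.csv", window_table)
        emit("lloyd_taylor.csv", pd.DataFrame(lt_rows))
        emit("driver_table.csv", driver_table)
        emit("period_stats.csv", stats)
        emit("correlations.csv", correlations)
        emit("path_coefficients.csv", pd.DataFrame(path_rows))
        if indirect_rows:
            emit("indirect_effects.csv", pd.concat(indirect_rows, ignore_index=True))
        log_path = outdir / "run_log.txt"
        log_path.write_text("\n".join(log) + "\n")
        written.append(log_path)
        manifest = {
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config),
            "outputs": sorted(p.name for p in written),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err
    return {"outdir": outdir, "log": log, "config_hash": config.config_hash()}
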