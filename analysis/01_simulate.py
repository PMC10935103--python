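"""Generate the synthetic five-year tower bundle the analyses run on.

Writes half-hourly records (with injected gaps and low-u* night episodes),
the generating truth, the daily LAI series and the phenology calendar under
results/synthetic/.  Five years, 2011-2015: odd years (2011, 2013, 2015) are
on-years (mass shooting), even years off-years.
"""

from pathlib import Path

import pandas as pd

from bambooflux.pipeline import simulate_command

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 1

if __name__ == "__main__":
    paths = simulate_command(OUT, years=5, seed=SEED, start_year=2011, n_random_gaps=100)
    data = pd.read_csv(paths["data"])
    mask = pd.read_csv(paths["mask"])
    n_gap = int(data["nee"].isna().sum())
    n_low = int(mask["low_ustar"].sum())
    print(f"wrote {len(data)} half-hourly records to {paths['data']}")
    print(f"  NEE gaps injected: {n_gap}; low-u* night episodes: {n_low}")
    print(f"  calendar: on-years 2011/2013/2015, off-years 2012/2014 -> {paths['calendar']}")
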