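"""Published reference flux means for the Anji Moso bamboo tower.

Five years (2011-2015) of station results are summarized by published mean
NEE and RE per phenology period (gC m-2 per 5 days) and per year class
(gC m-2 a-1).  The raw tower record is not deposited, so these printed
means serve two purposes here: they are the consistency oracle for the
pipeline's sign and aggregation conventions via the conservation identity

    GEP = RE - NEE,

and they anchor the magnitudes the synthetic generator aims for.  GEP is
never stored — it is always derived from NEE and RE through the identity.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PERIOD_MEANS", "ANNUAL_MEANS", "derive_gep_table"]

#: published mean (NEE, RE) per phenology period, gC m-2 per 5 days.
#: Negative NEE = carbon sink.
PERIOD_MEANS: dict[str, tuple[float, float]] = {
    "FG_ON": (-17.30, 26.24),
    "LS_ON": (-19.04, 29.08),
    "NF_ON": (-12.19, 21.48),
    "LR_OFF": (-11.75, 26.53),
    "LS_OFF": (-23.85, 26.39),
    "NF_OFF": (-3.37, 22.01),
}

#: published mean (NEE, RE) per year class, gC m-2 a-1.
ANNUAL_MEANS: dict[str, tuple[float, float]] = {
    "on": (-1071.99, 1799.41),
    "off": (-1051.70, 1777.79),
}


def derive_gep_table() -> pd.DataFrame:
    """GEP = RE - NEE applied to the published period and annual means."""
    rows = []
    for label, (nee, re) in PERIOD_MEANS.items():
        rows.append(
            {"stratum": label, "scale": "5day", "nee": nee, "re": re,
             "gep": re - nee}
        )
    for cls, (nee, re) in ANNUAL_MEANS.items():
        rows.append(
            {"stratum": cls, "scale": "annual", "nee": nee, "re": re,
             "gep": re - nee}
        )
    return pd.DataFrame(rows)
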