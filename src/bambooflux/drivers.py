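"""Driver attribution: Pearson correlation and path analysis.

Six biotic/abiotic factors (VPD, Prec, PAR, LAI, Ta, Ts) are related to
three carbon fluxes (NEE, RE, GEP) and two photosynthetic parameters
(Pmax, alpha) on the 5-day series, per phenology period and per year class.

Two complementary analyses:

* **Pearson correlation** between every factor and response within a
  stratum, with two-sided p-values and the usual * (p < 0.05) /
  ** (p < 0.01) flags.
* **Path analysis** over the fixed causal graph

      {VPD, Prec, PAR, LAI, Ta, Ts} -> Pmax      (photosynthetic capacity)
      {VPD, Prec, PAR, LAI, Ta, Ts} -> RE        (respiration)
      Pmax -> GEP,   GEP -> NEE,   RE -> NEE

  estimated by per-equation ordinary least squares on within-stratum
  z-standardized variables (classic path analysis).  Direct effects are the
  standardized coefficients; indirect factor->NEE effects multiply along the
  photosynthetic chain (factor->Pmax->GEP->NEE) and the respiration chain
  (factor->RE->NEE).  Under collinear factors coefficients may exceed |1|
  (suppression); that is permitted and flagged, and a singular design falls
  back to a tiny ridge penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FACTORS",
    "RESPONSES",
    "PATH_EDGES",
    "CHAINS",
    "pearson_matrix",
    "PathModelResult",
    "fit_path_model",
    "indirect_effects",
    "simulate_path_data",
]

FACTORS = ("vpd", "prec", "par", "lai", "ta", "ts")
RESPONSES = ("nee", "re", "gep", "pmax", "alpha")

#: the structural equations: endogenous variable -> its parents
PATH_EQUATIONS: dict[str, tuple[str, ...]] = {
    "pmax": FACTORS,
    "re": FACTORS,
    "gep": ("pmax",),
    "nee": ("gep", "re"),
}
PATH_EDGES: tuple[tuple[str, str], ...] = tuple(
    (parent, child) for child, parents in PATH_EQUATIONS.items() for parent in parents
)
#: factor -> NEE chains whose direct effects multiply into indirect effects
CHAINS = {
    "photosynthetic": ("pmax", "gep", "nee"),
    "respiration": ("re", "nee"),
}
MIN_STRATUM_N = 15
_RIDGE = 1e-8


def pearson_matrix(
    data: pd.DataFrame,
    strata: pd.Series | None = None,
    factors=FACTORS,
    responses=RESPONSES,
) -> pd.DataFrame:
    """Pearson r between every factor and response, per stratum.

    Pairwise-complete observations; strata with fewer than 3 complete
    pairs, or a zero-variance member, report NaN.  ``sig`` holds the
    ``*``/``**`` flags of the two-sided t-test at 0.05 / 0.01.
    """
    if strata is None:
        strata = pd.Series("all", index=data.index)
    rows = []
    for stratum in pd.unique(strata):
        block = data[strata == stratum]
        for x in factors:
            for y in responses:
                pair = block[[x, y]].dropna()
                n = len(pair)
                r = p = np.nan
                if n >= 3:
                    xv = pair[x].to_numpy(dtype=float)
                    yv = pair[y].to_numpy(dtype=float)
                    if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                        r, p = stats.pearsonr(xv, yv)
                sig = ""
                if np.isfinite(p):
                    sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")
                rows.append(
                    {
                        "stratum": stratum,
                        "factor": x,
                        "response": y,
                        "r": r,
                        "p": p,
                        "n": n,
                        "sig": sig,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PathModelResult:
    """Standardized direct effects on the fixed graph, plus diagnostics."""

    stratum: str
    direct: dict[tuple[str, str], float]
    r2: dict[str, float]
    n: int
    flags: list[str] = field(default_factory=list)

    def coefficient(self, parent: str, child: str) -> float:
        return self.direct[(parent, child)]


def _standardize(block: pd.DataFrame) -> pd.DataFrame:
    z = block - block.mean()
    sd = block.std(ddof=0)
    if (sd == 0).any():
        dead = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance variables in stratum: {dead}")
    return z / sd


def fit_path_model(
    data: pd.DataFrame,
    stratum: str = "all",
    strata: pd.Series | None = None,
    min_n: int = MIN_STRATUM_N,
) -> PathModelResult:
    """Per-equation standardized OLS over the fixed causal graph.

    Rows with any missing variable are dropped listwise within the
    stratum.  Coefficients beyond |1| are flagged (collinearity
    suppression), and a numerically singular design triggers a ridge
    fallback with penalty 1e-8 plus a warning flag.
    """
    variables = list(FACTORS) + ["pmax", "re", "gep", "nee"]
    block = data if strata is None else data[strata == stratum]
    block = block[variables].dropna()
    n = len(block)
    if n < min_n:
        raise ValueError(f"stratum {stratum!r} has n={n} < {min_n}")
    z = _standardize(block)

    direct: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    flags: list[str] = []
    for child, parents in PATH_EQUATIONS.items():
        X = z[list(parents)].to_numpy(dtype=float)
        y = z[child].to_numpy(dtype=float)
        gram = X.T @ X
        if np.linalg.cond(gram) > 1e12:
            flags.append(f"singular design for {child}; ridge fallback")
            beta = np.linalg.solve(gram + _RIDGE * np.eye(len(parents)), X.T @ y)
        else:
            beta = np.linalg.solve(gram, X.T @ y)
        resid = y - X @ beta
        r2[child] = float(1.0 - resid @ resid / (y @ y))
        for parent, b in zip(parents, beta):
            direct[(parent, child)] = float(b)
            if abs(b) > 1.0:
                flags.append(f"|PC| > 1 on {parent}->{child} (suppression)")
    return PathModelResult(stratum=stratum, direct=direct, r2=r2, n=n, flags=flags)


def indirect_effects(result: PathModelResult) -> pd.DataFrame:
    """Factor -> NEE effects as products along each causal chain.

    photosynthetic chain: PC(f->Pmax) * PC(Pmax->GEP) * PC(GEP->NEE);
    respiration chain:    PC(f->RE) * PC(RE->NEE);  total = their sum.
    """
    pc = result.coefficient
    photo_tail = pc("pmax", "gep") * pc("gep", "nee")
    resp_tail = pc("re", "nee")
    rows = []
    for f in FACTORS:
        photo = pc(f, "pmax") * photo_tail
        resp = pc(f, "re") * resp_tail
        rows.append(
            {
                "stratum": result.stratum,
                "factor": f,
                "photosynthetic": photo,
                "respiration": resp,
                "total": photo + resp,
            }
        )
    return pd.DataFrame(rows)


def simulate_path_data(
    coefficients: dict[tuple[str, str], float],
    n: int,
    seed: int,
    factor_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Linear-Gaussian data from the path graph with known standardized PCs.

    Exogenous factors are multivariate normal with unit variances and
    correlation ``factor_corr`` (identity by default); each endogenous
    variable is its parents' weighted sum plus Gaussian noise scaled so the
    population variance is exactly 1, making ``coefficients`` the true
    standardized path coefficients.  Raises if a structural part already
    has variance >= 1 (no admissible error variance).
    """
    k = len(FACTORS)
    R = np.eye(k) if factor_corr is None else np.asarray(factor_corr, dtype=float)
    rng = np.random.default_rng(seed)
    order = list(FACTORS) + ["pmax", "re", "gep", "nee"]
    cov = np.zeros((len(order), len(order)))
    cov[:k, :k] = R
    pos = {v: i for i, v in enumerate(order)}
    data = np.zeros((n, len(order)))
    data[:, :k] = rng.multivariate_normal(np.zeros(k), R, size=n)
    for child, parents in PATH_EQUATIONS.items():
        a = np.array([coefficients[(p, child)] for p in parents])
        ip = [pos[p] for p in parents]
        var_struct = a @ cov[np.ix_(ip, ip)] @ a
        if var_struct >= 1.0:
            raise ValueError(
                f"structural variance of {child} is {var_struct:.3f} >= 1"
            )
        sigma = np.sqrt(1.0 - var_struct)
        i = pos[child]
        data[:, i] = data[:, ip] @ a + sigma * rng.standard_normal(n)
        cov[i, :] = cov[:, i] = cov[np.ix_(ip, range(len(order)))].T @ a
        cov[i, i] = 1.0
    return pd.DataFrame(data, columns=order)
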