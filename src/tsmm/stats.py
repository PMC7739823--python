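"""Cohort statistics: Mann-Whitney rank-sum tests (exact or approximate),
step-down Holm-Bonferroni correction, linear regression, and assembly of
the three cohort report tables.

Dialect notes, since rank-sum implementations differ:

* The exact Mann-Whitney two-sided p is twice the lower tail probability of
  ``min(U_ab, U_ba)`` under full enumeration of group assignments, capped
  at 1.  The exact path is used when the pooled sample has no ties and
  ``n_a + n_b <= 25`` (enumeration is instant at cohort scale); otherwise a
  normal approximation with midrank tie correction and continuity
  correction is used.
* Holm adjustment is the step-down multiply-and-monotonize rule and is
  UNCAPPED by default, so adjusted p-values above 1 are reported as such
  (``cap=True`` restores the conventional ``min(1, .)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_TOTAL_N_CUTOFF = 25

MUSCLES = ("PS", "AS", "MG", "LG")


@dataclass
class MannWhitneyResult:
    u_statistic: float  # U of the first sample
    p_value: float
    method: str  # "exact" or "normal"
    n_a: int
    n_b: int


@dataclass
class GroupComparison:
    measure: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    p_adjusted: float | None = None
    family: str | None = None


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Null distribution of the Mann-Whitney U statistic (no ties).

    Returns counts of arrangements giving each U in 0..n*m for samples of
    sizes n and m, via the standard recursion
    ``N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1)``.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # first sample element is the overall maximum
    b = _u_counts(n, m - 1)  # second sample element is the overall maximum
    out = []
    for u in range(n * m + 1):
        c = 0
        if 0 <= u - m < len(a):
            c += a[u - m]
        if u < len(b):
            c += b[u]
        out.append(c)
    return tuple(out)


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank-sum test.

    U is computed from midranks; see the module docstring for the exact /
    normal-approximation dialect.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    u_b = n * m - u_a
    u_min = min(u_a, u_b)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n + m <= EXACT_TOTAL_N_CUTOFF:
        counts = _u_counts(n, m)
        total = sum(counts)
        cdf = sum(counts[: int(u_min) + 1]) / total
        p = min(1.0, 2.0 * cdf)
        method = "exact"
    else:
        big_n = n + m
        mu = n * m / 2.0
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
        var = n * m / 12.0 * (big_n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u_min - mu + 0.5) / np.sqrt(var)  # continuity toward center
            p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal"
    return MannWhitneyResult(u_statistic=u_a, p_value=float(p), method=method, n_a=n, n_b=m)


def holm_bonferroni(p_values, cap: bool = False) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order.

    Sorted ascending, ``p_(i)`` is multiplied by ``m - i + 1`` and the
    sequence made monotone non-decreasing.  Uncapped by default: adjusted
    values may exceed 1 (pass ``cap=True`` for ``min(1, .)``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a 1-D family of at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (m - np.arange(m))
    adjusted = np.maximum.accumulate(adjusted)
    if cap:
        adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least-squares line with R^2 and the two-sided slope p.

    The slope p-value is from ``t = slope / SE`` on ``n - 2`` degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 matched observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def compare_groups(df: pd.DataFrame, measure: str, group_col: str = "group") -> GroupComparison:
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = df.loc[df[group_col] == groups[0], measure].to_numpy(dtype=float)
    b = df.loc[df[group_col] == groups[1], measure].to_numpy(dtype=float)
    mw = mann_whitney(a, b)
    return GroupComparison(
        measure=measure,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        u_statistic=mw.u_statistic,
        p_value=mw.p_value,
    )


def _ensure_derived(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived per-subject columns (height*mass, normalized/relative
    volumes, CSA ratios) when the raw columns are present."""
    df = df.copy()
    if "height_mass_kgm" not in df and {"height_m", "mass_kg"} <= set(df):
        df["height_mass_kgm"] = df["height_m"] * df["mass_kg"]
    vol_cols = {m: f"vol_{m.lower()}_cm3" for m in MUSCLES}
    if "vol_total_cm3" not in df and set(vol_cols.values()) <= set(df):
        df["vol_total_cm3"] = sum(df[c] for c in vol_cols.values())
    if "vol_total_cm3" in df:
        for m, c in vol_cols.items():
            if c in df:
                if f"norm_{m.lower()}" not in df and "height_mass_kgm" in df:
                    df[f"norm_{m.lower()}"] = df[c] / df["height_mass_kgm"]
                if f"rel_{m.lower()}_pct" not in df:
                    df[f"rel_{m.lower()}_pct"] = 100.0 * df[c] / df["vol_total_cm3"]
        if "norm_total" not in df and "height_mass_kgm" in df:
            df["norm_total"] = df["vol_total_cm3"] / df["height_mass_kgm"]
    if "tendon_csa_mm2" in df:
        csa_cm2 = df["tendon_csa_mm2"] / 100.0
        for m, c in vol_cols.items():
            if c in df and f"csa_per_vol_{m.lower()}_cm" not in df:
                df[f"csa_per_vol_{m.lower()}_cm"] = csa_cm2 / df[c]
        if "vol_total_cm3" in df and "csa_per_vol_total_cm" not in df:
            df["csa_per_vol_total_cm"] = csa_cm2 / df["vol_total_cm3"]
        if "height_mass_kgm" in df and "csa_per_heightmass" not in df:
            df["csa_per_heightmass"] = df["tendon_csa_mm2"] / df["height_mass_kgm"]
    return df


#: Table-2-style measure families: each family repeats one measure over the
#: four individual muscles and is Holm-corrected as a unit; the total-column
#: test of each measure is a single test and stays unadjusted.
TABLE2_FAMILIES = {
    "muscle_volume_cm3": [f"vol_{m.lower()}_cm3" for m in MUSCLES] + ["vol_total_cm3"],
    "normalized_volume_cm3_per_kgm": [f"norm_{m.lower()}" for m in MUSCLES] + ["norm_total"],
    "relative_volume_pct": [f"rel_{m.lower()}_pct" for m in MUSCLES],
    "tendon_csa_per_volume_cm": [f"csa_per_vol_{m.lower()}_cm" for m in MUSCLES]
    + ["csa_per_vol_total_cm"],
}

TABLE1_MEASURES = [
    "age_years",
    "height_m",
    "mass_kg",
    "tendon_csa_mm2",
    "moment_arm_mm",
    "peak_torque_nm",
    "stride_length_m",
    "step_length_m",
    "stride_time_s",
    "cadence_steps_per_min",
]

TABLE3_ROWS = ["height_mass_kgm", "tendon_csa_mm2", "peak_torque_nm", "tendon_force_n"]
TABLE3_COLS = [f"vol_{m.lower()}_cm3" for m in MUSCLES] + ["vol_total_cm3"]


def build_tables(
    measures: pd.DataFrame, alpha: float = 0.05, cap_p: bool = False
) -> dict:
    """Assemble the three cohort reports from a per-subject measures table.

    Returns ``{"table1": ..., "table2": ..., "table3": ...}`` DataFrames:
    group means +/- SD with Mann-Whitney p per measure (table 1); muscle
    volume measures with Holm adjustment over the four per-muscle tests
    within each measure family (table 2); and per-group regressions of body
    size, tendon CSA, peak torque and tendon force against each muscle
    volume (table 3).  Rows whose measures are missing for any subject are
    skipped with a logged warning.
    """
    df = _ensure_derived(measures)
    groups = list(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")

    def usable(col: str) -> bool:
        if col not in df:
            logger.warning("measure %r missing; row skipped", col)
            return False
        if df[col].isna().any():
            logger.warning("measure %r incomplete; row skipped", col)
            return False
        return True

    rows1 = []
    for col in TABLE1_MEASURES:
        if not usable(col):
            continue
        c = compare_groups(df, col)
        rows1.append(
            {
                "measure": col,
                f"mean_{groups[0]}": c.mean_a,
                f"sd_{groups[0]}": c.sd_a,
                f"mean_{groups[1]}": c.mean_b,
                f"sd_{groups[1]}": c.sd_b,
                "U": c.u_statistic,
                "p_value": c.p_value,
                "significant": c.p_value < alpha,
            }
        )
    table1 = pd.DataFrame(rows1)

    rows2 = []
    for family, cols in TABLE2_FAMILIES.items():
        cols = [c for c in cols if usable(c)]
        muscle_cols = [c for c in cols if not c.endswith(("total", "total_cm3", "total_cm"))]
        comps = {c: compare_groups(df, c) for c in cols}
        if muscle_cols:
            adj = holm_bonferroni([comps[c].p_value for c in muscle_cols], cap=cap_p)
            adj_map = dict(zip(muscle_cols, adj))
        else:
            adj_map = {}
        for c in cols:
            comp = comps[c]
            p_adj = adj_map.get(c)
            p_eff = p_adj if p_adj is not None else comp.p_value
            rows2.append(
                {
                    "family": family,
                    "measure": c,
                    f"mean_{groups[0]}": comp.mean_a,
                    f"sd_{groups[0]}": comp.sd_a,
                    f"mean_{groups[1]}": comp.mean_b,
                    f"sd_{groups[1]}": comp.sd_b,
                    "U": comp.u_statistic,
                    "p_raw": comp.p_value,
                    "p_adjusted": p_adj,
                    "significant": p_eff < alpha,
                }
            )
    table2 = pd.DataFrame(rows2)

    rows3 = []
    for yrow in TABLE3_ROWS:
        if not usable(yrow):
            continue
        for xcol in TABLE3_COLS:
            if not usable(xcol):
                continue
            for g in groups:
                sub = df[df["group"] == g]
                try:
                    fit = linear_regression(sub[xcol], sub[yrow])
                except ValueError as exc:
                    logger.warning(
                        "regression %s ~ %s (%s) skipped: %s", yrow, xcol, g, exc
                    )
                    continue
                rows3.append(
                    {
                        "response": yrow,
                        "muscle_volume": xcol,
                        "group": g,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "p_value": fit.p_value,
                        "n": fit.n,
                        "significant": fit.p_value < alpha,
                    }
                )
    table3 = pd.DataFrame(rows3)
    return {"table1": table1, "table2": table2, "table3": table3}
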