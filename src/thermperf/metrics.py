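"""Acclimation capacity and the generalist-specialist trade-off regressions.

Acclimation capacity compares performance measured at the temperature each
fish was acclimated to:

    capacity = 1 - (P28 - P20) / ((P28 + P20) / 2)

where P20 is Ucrit of the cold-acclimated fish tested at 20 °C and P28 of
the same fish warm-acclimated and tested at 28 °C. Perfect thermal
compensation (P20 = P28) gives capacity 1; values below 1 mean the cold
phenotype underperforms its warm counterpart, values above 1 that it
outperforms it.

Trade-offs among capacity, maximum performance and performance breadth are
quantified by ordinary least-squares regressions within each acclimation
treatment, with sexes pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


@dataclass
class RegressionResult:
    """Simple OLS y ~ x with the F-test of the slope."""

    slope: float
    intercept: float
    r2: float
    f_stat: float
    df1: int
    df2: int
    p: float
    n: int


def acclimation_capacity(p28: float, p20: float) -> float:
    """Thermal-compensation index from the matched-condition performances."""
    if p28 <= 0 or p20 <= 0:
        raise MetricError("performances must be positive")
    return 1.0 - (p28 - p20) / ((p28 + p20) / 2.0)


def build_capacity_table(observations: pd.DataFrame) -> pd.DataFrame:
    """One capacity record per fish measured under both matched conditions.

    P20 is the row with acclimation 20 °C / test 20 °C, P28 the row with
    28 °C / 28 °C. Fish missing either condition are dropped (count logged).
    """
    obs = observations
    p20 = obs[(obs["accl_temp_c"] == 20.0) & (obs["test_temp_c"] == 20.0)]
    p28 = obs[(obs["accl_temp_c"] == 28.0) & (obs["test_temp_c"] == 28.0)]
    merged = pd.merge(
        p20[["fish_id", "ucrit_bl_s"]].rename(columns={"ucrit_bl_s": "p20"}),
        p28[["fish_id", "ucrit_bl_s"]].rename(columns={"ucrit_bl_s": "p28"}),
        on="fish_id", how="inner")
    n_dropped = obs["fish_id"].nunique() - len(merged)
    if n_dropped:
        log.warning("dropped %d fish missing a matched condition", n_dropped)
    if merged.empty:
        raise MetricError("no fish has both matched conditions measured")
    merged["capacity"] = [acclimation_capacity(r.p28, r.p20)
                          for r in merged.itertuples()]
    return merged


def ols(x, y) -> RegressionResult:
    """Simple linear regression with R^2 and the F-test of the slope.

    F = r2 * df2 / (1 - r2) with df = (1, n - 2); for a perfectly collinear
    response the F statistic is infinite and p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise MetricError("x and y must be 1-d and equally long")
    n = len(x)
    if n < 3:
        raise MetricError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise MetricError("x is constant")
    fit = stats.linregress(x, y)
    # constant y: zero slope, no explained variance (linregress yields nan r)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue ** 2)
    df2 = n - 2
    if np.isclose(r2, 1.0):
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 * df2 / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, df2))
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept), r2=r2,
                            f_stat=f_stat, df1=1, df2=df2, p=p, n=n)


#: The six trade-off regressions: (response, predictor) per treatment.
TRADEOFF_PAIRS = (("p_max", "capacity"),
                  ("breadth_width", "capacity"),
                  ("breadth_width", "p_max"))


def tradeoff_report(curve_summaries: pd.DataFrame,
                    capacity_table: pd.DataFrame) -> pd.DataFrame:
    """Trade-off regressions within each acclimation treatment.

    Uses only individuals whose curve passed the inclusion filter,
    intersected with the fish for which capacity is defined; sexes pooled.
    Cells with fewer than 3 usable fish are flagged rather than fatal.
    """
    included = curve_summaries[curve_summaries["included"]]
    data = included.merge(capacity_table[["fish_id", "capacity"]],
                          on="fish_id", how="inner")
    rows = []
    for accl, grp in data.groupby("accl_temp_c"):
        treatment = "cold" if float(accl) == 20.0 else "warm"
        for response, predictor in TRADEOFF_PAIRS:
            base = {"treatment": treatment, "accl_temp_c": float(accl),
                    "response": response, "predictor": predictor,
                    "n": len(grp)}
            try:
                r = ols(grp[predictor], grp[response])
            except MetricError as exc:
                rows.append({**base, "flag": f"underpowered: {exc}"})
                continue
            rows.append({**base, "slope": r.slope, "intercept": r.intercept,
                         "r2": r.r2, "f_stat": r.f_stat, "df1": r.df1,
                         "df2": r.df2, "p": r.p, "flag": ""})
    return pd.DataFrame(rows)
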