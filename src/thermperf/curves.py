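"""Per-fish quadratic thermal performance curves and 80% performance breadth.

Each fish x acclimation series (three test temperatures) is fitted with a
concave quadratic on the raw performance scale (body lengths per second,
uncentered temperature axis). The optimum follows from the vanishing
derivative, the performance breadth from the roots of the quadratic shifted
down to the threshold fraction of the maximum, and individuals whose optimum
falls at or beyond the top test temperature are excluded because the maximum
cannot be located reliably there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FRACTION = 0.8
DEFAULT_T_CUT = 32.0  # °C


class CurveFitError(ValueError):
    pass


@dataclass
class QuadFit:
    """Least-squares quadratic perf = a*T^2 + b*T + c on raw temperature."""

    fish_id: str
    accl_temp: float
    a: float
    b: float
    c: float
    n_points: int
    scale: str = "raw_bl_s"

    def __call__(self, temp):
        return self.a * np.asarray(temp, float) ** 2 + self.b * np.asarray(
            temp, float) + self.c


@dataclass
class CurveSummary:
    fish_id: str
    accl_temp: float
    a: float
    b: float
    c: float
    t_opt: float
    p_max: float
    breadth_lo: float
    breadth_hi: float
    breadth_width: float
    included: bool
    exclusion_reason: str  # convex | t_opt_ge_cut | nonpositive_max | none


def fit_quadratic(temps, perf, fish_id: str = "", accl_temp: float = np.nan,
                  ) -> QuadFit:
    """Fit perf = a*T^2 + b*T + c by least squares.

    With exactly three distinct temperatures the quadratic interpolates the
    points exactly.
    """
    temps = np.asarray(temps, float)
    perf = np.asarray(perf, float)
    if temps.shape != perf.shape or temps.ndim != 1:
        raise CurveFitError("temps and perf must be 1-d and equally long")
    if np.unique(temps).size < 3:
        raise CurveFitError("need at least 3 distinct temperatures")
    a, b, c = np.polyfit(temps, perf, 2)
    return QuadFit(fish_id=fish_id, accl_temp=float(accl_temp),
                   a=float(a), b=float(b), c=float(c), n_points=len(temps))


def vertex(fit: QuadFit) -> tuple[float, float]:
    """Optimum temperature and maximum performance from f'(T) = 0.

    t_opt = -b / (2a), p_max = c - b^2 / (4a); requires a concave curve.
    """
    if fit.a >= 0:
        raise CurveFitError("curve is not concave (a >= 0); no maximum")
    t_opt = -fit.b / (2.0 * fit.a)
    p_max = fit.c - fit.b ** 2 / (4.0 * fit.a)
    return float(t_opt), float(p_max)


def breadth(fit: QuadFit, fraction: float = DEFAULT_FRACTION,
            ) -> tuple[float, float, float]:
    """Temperature interval where performance >= fraction of the maximum.

    Solves a*T^2 + b*T + (c - fraction * p_max) = 0 with the quadratic
    formula. The closed-form width 2*sqrt((1 - fraction) * p_max / -a) is an
    algebraically equivalent cross-check used by the test-suite.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    t_opt, p_max = vertex(fit)
    if p_max <= 0:
        raise CurveFitError("nonpositive maximum; the threshold exceeds "
                            "the curve everywhere")
    a, b = fit.a, fit.b
    c_shift = fit.c - fraction * p_max
    disc = b * b - 4.0 * a * c_shift
    sq = math.sqrt(disc)
    lo = (-b + sq) / (2.0 * a)   # a < 0: +sq gives the smaller root
    hi = (-b - sq) / (2.0 * a)
    return float(lo), float(hi), float(hi - lo)


def summarize_curve(fit: QuadFit, fraction: float = DEFAULT_FRACTION,
                    t_cut: float = DEFAULT_T_CUT) -> CurveSummary:
    """Derive optimum, maximum, breadth and the inclusion decision."""
    base = dict(fish_id=fit.fish_id, accl_temp=fit.accl_temp,
                a=fit.a, b=fit.b, c=fit.c)
    nan = float("nan")
    if fit.a >= 0:  # flat curves count as convex: no interior maximum
        return CurveSummary(**base, t_opt=nan, p_max=nan, breadth_lo=nan,
                            breadth_hi=nan, breadth_width=nan,
                            included=False, exclusion_reason="convex")
    t_opt, p_max = vertex(fit)
    if p_max <= 0:
        return CurveSummary(**base, t_opt=t_opt, p_max=p_max, breadth_lo=nan,
                            breadth_hi=nan, breadth_width=nan,
                            included=False,
                            exclusion_reason="nonpositive_max")
    lo, hi, width = breadth(fit, fraction)
    if t_opt >= t_cut:  # strict cut: the optimum must lie inside the grid
        return CurveSummary(**base, t_opt=t_opt, p_max=p_max, breadth_lo=lo,
                            breadth_hi=hi, breadth_width=width,
                            included=False, exclusion_reason="t_opt_ge_cut")
    return CurveSummary(**base, t_opt=t_opt, p_max=p_max, breadth_lo=lo,
                        breadth_hi=hi, breadth_width=width, included=True,
                        exclusion_reason="none")


def curve_summaries(table: pd.DataFrame, fraction: float = DEFAULT_FRACTION,
                    t_cut: float = DEFAULT_T_CUT,
                    perf_col: str = "ucrit_bl_s") -> pd.DataFrame:
    """Quadratic summaries for every fish x acclimation series.

    Runs on the raw BL s^-1 scale: the breadth threshold is a fraction of
    the maximum, which is only meaningful for a positive-valued response.
    """
    rows = []
    for (fish, accl), grp in table.groupby(["fish_id", "accl_temp_c"],
                                           sort=True):
        if grp["test_temp_c"].nunique() < 3:
            continue  # incomplete series (e.g. pump failure): no curve
        fit = fit_quadratic(grp["test_temp_c"], grp[perf_col],
                            fish_id=str(fish), accl_temp=float(accl))
        rows.append(summarize_curve(fit, fraction=fraction, t_cut=t_cut).__dict__)
    if not rows:
        raise CurveFitError("no fish had >= 3 distinct test temperatures")
    out = pd.DataFrame(rows).rename(columns={"accl_temp": "accl_temp_c"})
    out.attrs["scale"] = "raw_bl_s"
    out.attrs["fraction"] = fraction
    out.attrs["t_cut"] = t_cut
    return out


def filter_individuals(summaries: pd.DataFrame, t_cut: float = DEFAULT_T_CUT,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split summaries into the included subset and an exclusion report.

    The report counts exclusions per reason and, per acclimation treatment,
    the fraction of fish whose optimum lies at or above the cut temperature
    (those whose maximum the test grid cannot bracket).
    """
    included = summaries[summaries["included"]].copy()
    rows = []
    for accl, grp in summaries.groupby("accl_temp_c"):
        n = len(grp)
        counts = grp["exclusion_reason"].value_counts()
        rows.append({
            "accl_temp_c": accl,
            "n_curves": n,
            "n_included": int(grp["included"].sum()),
            "n_convex": int(counts.get("convex", 0)),
            "n_t_opt_ge_cut": int(counts.get("t_opt_ge_cut", 0)),
            "n_nonpositive_max": int(counts.get("nonpositive_max", 0)),
            "frac_t_opt_ge_cut": float((grp["t_opt"] >= t_cut).sum() / n)
            if n else float("nan"),
        })
    return included, pd.DataFrame(rows)
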