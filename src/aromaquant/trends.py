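"""Trend regressions: threshold-MW, storage-day decay, and OAV vs. D/T.

All fits are ordinary least squares with the two-sided t-test p-value on the
slope.  Logarithms are base 10 throughout: the base only shifts intercepts
in log-log fits but scales the slope in semi-log (per-day) fits, and base 10
matches the magnitude class of the study's printed decay slopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .odor import select_threshold
from .registry import Compound

__all__ = [
    "TrendFit",
    "ols_fit",
    "threshold_mw_regression",
    "intensity_trend",
    "oav_dt_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendFit:
    """Simple-regression summary: y = slope*x + intercept."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def ols_fit(x, y) -> TrendFit:
    """Ordinary least squares of y on x with slope t-test p-value.

    With n = 2 the line interpolates exactly and the p-value is reported as
    1.0 (no residual degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant: degenerate regression design")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = 1.0 if x.size < 3 or math.isnan(res.pvalue) else float(res.pvalue)
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept),
                    r2=r2, p_value=p, n=int(x.size))


def threshold_mw_regression(compounds: list[Compound], stat: str = "max",
                            scope: str = "pooled",
                            exclude: set[str] | None = None,
                            min_group_size: int = 3):
    """Regress log10(odor threshold, ppbv) on molecular weight.

    Only threshold-bearing compounds participate; ``stat`` selects the
    threshold statistic per compound (max / min / geomean).  ``scope`` is
    ``"pooled"`` (one fit, returned as a TrendFit) or ``"per-group"`` (dict
    of group -> TrendFit; groups with fewer than ``min_group_size``
    threshold-bearing members are skipped with a warning).  ``exclude``
    drops named compounds (explicit outlier lists; no automated trimming).
    """
    exclude = exclude or set()
    rows = [(c.group, c.mw, math.log10(select_threshold(c.thresholds, stat)))
            for c in compounds
            if c.has_threshold and c.name not in exclude]
    if scope == "pooled":
        if len(rows) < 3:
            raise ValueError("need >= 3 threshold-bearing compounds")
        return ols_fit([r[1] for r in rows], [r[2] for r in rows])
    if scope != "per-group":
        raise ValueError(f"unknown scope {scope!r}")
    fits: dict[str, TrendFit] = {}
    groups = sorted({r[0] for r in rows})
    for g in groups:
        sub = [r for r in rows if r[0] == g]
        if len(sub) < min_group_size:
            logger.warning("group %s: only %d threshold-bearing compounds; "
                           "skipped", g, len(sub))
            continue
        fits[g] = ols_fit([r[1] for r in sub], [r[2] for r in sub])
    return fits


def intensity_trend(days, intensity) -> TrendFit:
    """Fit log10(odor intensity) against storage day.

    ``intensity`` may be any positive per-day odor measure (summed OAV,
    dilution-to-threshold ratio, ...).
    """
    days = np.asarray(days, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        bad = days[intensity <= 0]
        raise ValueError(f"non-positive intensity at day(s) {bad.tolist()}")
    return ols_fit(days, np.log10(intensity))


def oav_dt_correlation(oav_sums: dict, dt_ratios: dict) -> TrendFit:
    """Log-log regression of summed OAV on the dilution-to-threshold ratio.

    Both inputs map day -> positive value and must cover the same days.
    """
    if set(oav_sums) != set(dt_ratios):
        raise ValueError(f"unpaired days: OAV has {sorted(oav_sums)}, "
                         f"D/T has {sorted(dt_ratios)}")
    days = sorted(oav_sums)
    o = np.array([oav_sums[d] for d in days], dtype=float)
    dt = np.array([dt_ratios[d] for d in days], dtype=float)
    if np.any(o <= 0) or np.any(dt <= 0):
        raise ValueError("OAV sums and D/T ratios must be positive")
    return ols_fit(np.log10(dt), np.log10(o))
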