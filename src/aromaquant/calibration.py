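"""Effective-carbon-number response model and external calibration.

A GC-MS detector's response factor (RF, peak-area units per ng of analyte)
is measured directly for the compounds in the working standard; every other
detected volatile ("CLASS": compounds lacking authentic standards or
surrogates) is quantified through a linear regression of RF on the effective
carbon number (ECN).  The ECN scores a molecule by summing unitless
carbon-number-equivalent contributions of its atoms and oxygen moieties:

    ECN = n_C*1 + n_H*(-0.035) + n_O*0 + n_carbonyl*(-0.95)
          + n_ether*0.55 + n_methyl*0.15

Mass collected on the sorbent tube converts to a headspace concentration via
the sampling geometry (default 50 mL/min for 1 min), and ppbv <-> ug/m^3
conversion uses an ideal-gas molar volume of 24.5 L/mol (25 degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .registry import MoietyCounts

__all__ = [
    "DEFAULT_MOLAR_VOLUME",
    "EcnCoefficients",
    "CalibrationFit",
    "RFModel",
    "SamplingGeometry",
    "DegenerateDesignError",
    "CalibrationRangeError",
    "compute_ecn",
    "fit_calibration_curve",
    "rf_cv",
    "rf_rse",
    "fit_rf_vs_ecn",
    "predict_rf",
    "quantify",
    "ppb_to_ugm3",
    "ugm3_to_ppb",
]

#: L/mol; back-derived from the study's printed dual-unit concentration pairs.
DEFAULT_MOLAR_VOLUME = 24.5


class DegenerateDesignError(ValueError):
    """Calibration or regression design with no spread in the predictor."""


class CalibrationRangeError(ValueError):
    """A predicted response factor fell outside the physical range (<= 0)."""


@dataclass(frozen=True)
class EcnCoefficients:
    """Per-atom/per-moiety carbon-number-equivalent contributions."""

    c_C: float = 1.0
    c_H: float = -0.035
    c_O: float = 0.0
    c_carbonyl: float = -0.95
    c_ether: float = 0.55
    c_methyl: float = 0.15

    def __post_init__(self) -> None:
        for name in ("c_C", "c_H", "c_O", "c_carbonyl", "c_ether", "c_methyl"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def compute_ecn(m: MoietyCounts, k: EcnCoefficients = EcnCoefficients()) -> float:
    """Effective carbon number of a molecule from its moiety counts."""
    return (m.n_C * k.c_C + m.n_H * k.c_H + m.n_O * k.c_O
            + m.n_carbonyl * k.c_carbonyl + m.n_ether * k.c_ether
            + m.n_methyl * k.c_methyl)


@dataclass(frozen=True)
class CalibrationFit:
    """External calibration of one compound: area vs. loading (ng)."""

    compound: str
    rf: float          # peak-area units per ng
    r2: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.rf > 0:
            raise ValueError(f"{self.compound}: rf must be > 0, got {self.rf}")
        if len(self.points) < 2:
            raise ValueError(f"{self.compound}: need >= 2 calibration points")


@dataclass(frozen=True)
class RFModel:
    """Linear model RF = slope * ECN + intercept over the standards."""

    slope: float
    intercept: float
    r2: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("RF-ECN model needs >= 2 standards")


@dataclass(frozen=True)
class SamplingGeometry:
    """Headspace sampling: flow rate (mL/min) x duration (min) -> volume (m^3)."""

    flow_rate_ml_min: float = 50.0
    duration_min: float = 1.0
    sampled_volume_m3: float = field(init=False)

    def __post_init__(self) -> None:
        vol = self.flow_rate_ml_min * self.duration_min * 1e-6
        if not vol > 0:
            raise ValueError("sampled volume must be positive")
        object.__setattr__(self, "sampled_volume_m3", vol)


def fit_calibration_curve(points, compound: str = "",
                          estimator: str = "zero_intercept") -> CalibrationFit:
    """Fit a response factor from (loading ng, peak area) pairs.

    The default estimator is the zero-intercept least-squares slope of area
    on loading (external calibration through the origin); ``estimator=
    "mean_ratio"`` averages the per-point area/loading ratios instead.
    R^2 is computed against the through-origin fit in both cases.
    """
    pts = [(float(x), float(a)) for x, a in points]
    if len(pts) < 2:
        raise DegenerateDesignError("need at least two calibration points")
    x = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    if np.any(x <= 0) or np.any(a < 0):
        raise ValueError("loadings must be > 0 and areas >= 0")
    if np.allclose(x, x[0]):
        raise DegenerateDesignError("all calibration loadings are identical")
    if estimator == "zero_intercept":
        rf = float(np.dot(x, a) / np.dot(x, x))
    elif estimator == "mean_ratio":
        rf = float(np.mean(a / x))
    else:
        raise ValueError(f"unknown rf estimator {estimator!r}")
    resid = a - rf * x
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return CalibrationFit(compound=compound, rf=rf, r2=min(r2, 1.0),
                          points=tuple(pts))


def _spread_stats(values, stat_name: str) -> tuple[float, float, int]:
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError(f"{stat_name} needs at least two values, got {v.size}")
    mean = float(v.mean())
    if not mean > 0:
        raise ValueError(f"{stat_name}: mean must be > 0, got {mean}")
    return mean, float(v.std(ddof=1)), int(v.size)


def rf_cv(rf_values) -> float:
    """Coefficient of variation, percent: 100 * SD / mean (sample SD, n-1)."""
    mean, sd, _ = _spread_stats(rf_values, "rf_cv")
    return 100.0 * sd / mean


def rf_rse(repeat_values) -> float:
    """Relative standard error, percent: 100 * (SD / sqrt(n)) / mean."""
    mean, sd, n = _spread_stats(repeat_values, "rf_rse")
    return 100.0 * (sd / math.sqrt(n)) / mean


def fit_rf_vs_ecn(standards) -> RFModel:
    """Ordinary least-squares line RF = slope*ECN + intercept over standards.

    ``standards`` is an iterable of (ecn, rf) pairs, one per calibration
    compound.
    """
    pts = [(float(e), float(r)) for e, r in standards]
    if len(pts) < 2:
        raise DegenerateDesignError("need at least two standards")
    e = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if np.allclose(e, e[0]):
        raise DegenerateDesignError("all ECN values identical")
    slope, intercept = np.polyfit(e, r, 1)
    pred = slope * e + intercept
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((r - pred) ** 2)) / ss_tot
    return RFModel(slope=float(slope), intercept=float(intercept),
                   r2=float(min(max(r2, 0.0), 1.0)), n_standards=len(pts))


def predict_rf(model: RFModel, ecn: float) -> float:
    """Predicted response factor at a given ECN; must be physically positive."""
    rf = model.slope * float(ecn) + model.intercept
    if rf <= 0:
        raise CalibrationRangeError(
            f"predicted RF {rf:.4g} at ECN {ecn:.4g} is non-positive "
            f"(outside the calibration range)"
        )
    return rf


def quantify(area: float, rf: float,
             geometry: SamplingGeometry = SamplingGeometry()) -> float:
    """Convert a peak area to a mass concentration in ug/m^3.

    mass_ng = area / rf; with the default 50 mL sample, 1 ng -> 20 ug/m^3.
    """
    if not rf > 0:
        raise ValueError(f"rf must be > 0, got {rf}")
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    mass_ng = area / rf
    return (mass_ng * 1e-3) / geometry.sampled_volume_m3  # ng -> ug


def ppb_to_ugm3(conc_ppb: float, mw: float,
                molar_volume: float = DEFAULT_MOLAR_VOLUME) -> float:
    """ppbv -> ug/m^3:  ug/m^3 = ppbv * MW / Vm  (Vm in L/mol)."""
    if not mw > 0 or not molar_volume > 0:
        raise ValueError("mw and molar_volume must be positive")
    return conc_ppb * mw / molar_volume


def ugm3_to_ppb(conc_ugm3: float, mw: float,
                molar_volume: float = DEFAULT_MOLAR_VOLUME) -> float:
    """Exact inverse of :func:`ppb_to_ugm3`."""
    if not mw > 0 or not molar_volume > 0:
        raise ValueError("mw and molar_volume must be positive")
    return conc_ugm3 * molar_volume / mw
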