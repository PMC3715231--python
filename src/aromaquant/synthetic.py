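"""Seeded generators for registry, calibration, study and sensory inputs.

The generators emulate the statistical structure a stored-fruit headspace
study assumes, so the whole pipeline is testable without instrument data:

* an ester-dominated fresh profile that peaks by storage day 3 and collapses
  by two orders of magnitude or more once decay starts;
* alcohols that are scarce while the fruit is fresh and peak at day 6;
* a linear response-factor-vs-ECN relation across compounds, with
  multiplicative lognormal measurement noise on peak areas;
* literature odor thresholds scattered lognormally around a class-dependent
  mean that decreases with molecular weight;
* a power-law link from summed odor activity to the panel-measured
  dilution-to-threshold (D/T) ratio.

Every function is a deterministic map of (scenario, seed): the same scenario
reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (EcnCoefficients, SamplingGeometry, compute_ecn,
                          ppb_to_ugm3)
from .registry import Compound, MoietyCounts, ThresholdRecord, compose_formula

__all__ = ["StudyScenario", "generate_registry", "generate_study", "generate_dt"]

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: Per-class concentration shape over the sampled days (relative units).
#: Esters rise to a day-3 peak then collapse >100-fold; alcohols peak at
#: day 6; the remaining classes fade gently during decay.
_SHAPES = {
    "ester":      {0: 1.0, 1: 0.85, 3: 3.0, 6: 0.003, 9: 0.0003},
    "alcohol":    {0: 0.005, 1: 0.012, 3: 0.08, 6: 10.0, 9: 0.25},
    "aldehyde":   {0: 1.0, 1: 1.0, 3: 4.0, 6: 0.4, 9: 0.3},
    "ketone":     {0: 1.0, 1: 1.2, 3: 0.08, 6: 0.003, 9: 0.01},
    "fatty_acid": {0: 1.0, 1: 0.75, 3: 0.7, 6: 0.08, 9: 0.03},
    "etc":        {0: 1.0, 1: 0.4, 3: 0.3, 6: 0.1, 9: 0.2},
}

#: Class-level log10 threshold (ppbv) at MW = 0; thresholds then fall with MW.
_THRESHOLD_INTERCEPT = {
    "ester": 3.0, "alcohol": 4.5, "aldehyde": 3.5,
    "ketone": 4.5, "fatty_acid": 3.5, "etc": 5.5,
}

_CAL_LOADINGS_NG = (1.30, 6.52, 13.0, 26.1, 65.2)


@dataclass(frozen=True)
class StudyScenario:
    """Generating conditions for a synthetic stored-fruit headspace study."""

    n_compounds: dict = field(default_factory=lambda: {
        "ester": 23, "alcohol": 11, "aldehyde": 5,
        "ketone": 5, "fatty_acid": 2, "etc": 7})
    days: tuple[int, ...] = (0, 1, 3, 6, 9)
    noise_sigma: float = 0.02          # lognormal sigma on peak areas
    rf_slope: float = 40.0             # generating RF-vs-ECN line
    rf_intercept: float = 5.0
    threshold_sigma: float = 0.5       # lognormal scatter across literature values
    threshold_mw_slope: float = -0.02  # d log10(threshold) / d MW
    dt_exponent: float = 0.5           # D/T ~ scale * (sum OAV)^exponent
    dt_scale: float = 1.0
    dt_sigma: float = 0.05
    n_standards: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        for name in ("rf_slope", "dt_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sigma", "threshold_sigma", "dt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])


def _make_molecule(group: str, n_c: int, rng: np.random.Generator):
    """Plausible C/H/O counts + moieties for one molecule of a class."""
    if group == "ester":
        counts = {"C": n_c, "H": 2 * n_c, "O": 2}
        n_me = min(int(rng.integers(2, 4)), (2 * n_c) // 3)
        m = MoietyCounts(n_c, 2 * n_c, 2, n_carbonyl=1, n_ether=1, n_methyl=n_me)
    elif group == "alcohol":
        counts = {"C": n_c, "H": 2 * n_c + 2, "O": 1}
        m = MoietyCounts(n_c, 2 * n_c + 2, 1, n_methyl=int(rng.integers(1, 3)))
    elif group in ("aldehyde", "ketone"):
        counts = {"C": n_c, "H": 2 * n_c, "O": 1}
        n_me = 1 if group == "aldehyde" else 2
        m = MoietyCounts(n_c, 2 * n_c, 1, n_carbonyl=1, n_methyl=n_me)
    elif group == "fatty_acid":
        counts = {"C": n_c, "H": 2 * n_c, "O": 2}
        m = MoietyCounts(n_c, 2 * n_c, 2, n_carbonyl=1, n_methyl=1)
    else:  # hydrocarbons
        counts = {"C": n_c, "H": 2 * n_c + 2}
        m = MoietyCounts(n_c, 2 * n_c + 2, 0, n_methyl=2)
    mw = sum(_ATOMIC_MASS[e] * n for e, n in counts.items())
    return compose_formula(counts), mw, m


def generate_registry(scenario: StudyScenario) -> list[Compound]:
    """Synthesise a compound registry matching the scenario's class counts.

    Thresholds (1-4 records per compound) are drawn lognormally around a
    class mean that decreases with molecular weight, emulating the inverse
    threshold-MW trend seen in literature surveys.
    """
    rng = scenario.rng(1)
    compounds: list[Compound] = []
    # standards spread across classes, largest classes first
    quota: list[str] = []
    order = sorted(scenario.n_compounds, key=lambda g: -scenario.n_compounds[g])
    while len(quota) < scenario.n_standards:
        for g in order:
            if quota.count(g) < scenario.n_compounds.get(g, 0):
                quota.append(g)
            if len(quota) >= scenario.n_standards:
                break
    for group in sorted(scenario.n_compounds):
        n = scenario.n_compounds[group]
        min_c = 3 if group in ("ester", "ketone") else 2
        for i in range(n):
            n_c = min_c + i % 8
            formula, mw, m = _make_molecule(group, n_c, rng)
            log_mean = (_THRESHOLD_INTERCEPT[group]
                        + scenario.threshold_mw_slope * mw)
            n_thr = int(rng.integers(1, 5))
            thresholds = tuple(
                ThresholdRecord(10.0 ** (log_mean + scenario.threshold_sigma
                                         * rng.standard_normal()),
                                f"synthetic-{j}")
                for j in range(n_thr))
            compounds.append(Compound(
                name=f"{group}-{n_c}C-{i + 1}", group=group, mw=mw,
                formula=formula, moieties=m, thresholds=thresholds,
                is_standard=quota.count(group) > i,
            ))
    return compounds


def generate_study(scenario: StudyScenario, registry: list[Compound],
                   geometry: SamplingGeometry = SamplingGeometry(),
                   coefficients: EcnCoefficients = EcnCoefficients()):
    """Simulate true concentrations and noisy peak areas for every compound.

    Returns ``(truth, areas, calibration)``:

    * ``truth`` — compound, group, day, conc_ppb, conc_ugm3 (generating
      values, noise-free);
    * ``areas`` — compound, day, area (observed, multiplicative lognormal
      noise applied);
    * ``calibration`` — compound, batch_day, loading_ng, area: five-point
      external calibration curves for the standards, one batch per day.
    """
    rng = scenario.rng(2)
    rf_true = {c.name: scenario.rf_slope * compute_ecn(c.moieties, coefficients)
               + scenario.rf_intercept for c in registry}
    bad = [n for n, rf in rf_true.items() if rf <= 0]
    if bad:
        raise ValueError(f"generating RF non-positive for {bad}")

    truth_rows, area_rows = [], []
    for c in registry:
        amplitude = float(rng.lognormal(mean=math.log(200.0), sigma=1.0))
        for day in scenario.days:
            ppb = amplitude * _SHAPES[c.group][day]
            ugm3 = ppb_to_ugm3(ppb, c.mw)
            mass_ng = ugm3 * geometry.sampled_volume_m3 * 1e3  # ug -> ng
            noise = (float(rng.lognormal(sigma=scenario.noise_sigma))
                     if scenario.noise_sigma > 0 else 1.0)
            truth_rows.append(dict(compound=c.name, group=c.group, day=day,
                                   conc_ppb=ppb, conc_ugm3=ugm3))
            area_rows.append(dict(compound=c.name, day=day,
                                  area=mass_ng * rf_true[c.name] * noise))

    cal_rows = []
    for c in registry:
        if not c.is_standard:
            continue
        for day in scenario.days:
            for load in _CAL_LOADINGS_NG:
                noise = (float(rng.lognormal(sigma=scenario.noise_sigma))
                         if scenario.noise_sigma > 0 else 1.0)
                cal_rows.append(dict(compound=c.name, batch_day=day,
                                     loading_ng=load,
                                     area=load * rf_true[c.name] * noise))
    return (pd.DataFrame(truth_rows), pd.DataFrame(area_rows),
            pd.DataFrame(cal_rows))


def generate_dt(oav_sums: dict, scenario: StudyScenario) -> dict:
    """Dilution-to-threshold ratios linked to summed OAV by a power law.

    dt(day) = dt_scale * (sum OAV)^dt_exponent * lognormal noise.
    """
    rng = scenario.rng(3)
    out = {}
    for day in sorted(oav_sums):
        v = float(oav_sums[day])
        if not v > 0:
            raise ValueError(f"day {day}: summed OAV must be positive")
        noise = (float(rng.lognormal(sigma=scenario.dt_sigma))
                 if scenario.dt_sigma > 0 else 1.0)
        out[day] = scenario.dt_scale * v**scenario.dt_exponent * noise
    return out
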