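"""Odor activity values (OAV) and relative proportions (RP).

OAV = concentration (ppbv) / odor threshold (ppbv): how many times over its
human detection threshold a volatile is present.  The relative proportion
RP = 100 * OAV / sum(OAV over the major-compound set, same day) apportions a
day's total odor activity among compounds.  Thresholds come from literature
surveys and frequently disagree between sources; a selection policy (max by
default, matching the source study's choice for consistency) picks the value
used.

Compounds without any threshold record are OAV-ineligible: they appear in
the output with a null OAV and are excluded from every sum and RP
denominator.  Below-detection entries likewise contribute nothing unless
``include_bdl`` is set.
"""

from __future__ import annotations

import logging
import math
from statistics import geometric_mean

import pandas as pd

from .profile import validate_concentration_table
from .registry import Compound, ThresholdRecord

__all__ = [
    "THRESHOLD_POLICIES",
    "select_threshold",
    "compute_oav",
    "build_oav_table",
    "relative_proportion",
    "sum_oav",
    "period_aggregate",
]

logger = logging.getLogger(__name__)

THRESHOLD_POLICIES = ("max", "min", "geomean")


class ThresholdIneligible(LookupError):
    """Raised when a compound has no threshold record to select from."""


def select_threshold(records, policy: str = "max") -> float:
    """Pick the working odor threshold (ppbv) from literature records."""
    values = [r.value if isinstance(r, ThresholdRecord) else float(r)
              for r in records]
    if not values:
        raise ThresholdIneligible("no threshold records")
    if policy == "max":
        return max(values)
    if policy == "min":
        return min(values)
    if policy == "geomean":
        return geometric_mean(values)
    raise ValueError(f"unknown threshold policy {policy!r}; "
                     f"choose from {THRESHOLD_POLICIES}")


def compute_oav(conc_ppb: float, threshold_ppb: float) -> float:
    """Odor activity value: concentration over threshold, both in ppbv."""
    if not threshold_ppb > 0:
        raise ValueError(f"threshold must be > 0 ppbv, got {threshold_ppb}")
    if conc_ppb < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_ppb}")
    return conc_ppb / threshold_ppb


def build_oav_table(conc_table: pd.DataFrame, compounds: list[Compound],
                    policy: str = "max", include_bdl: bool = False) -> pd.DataFrame:
    """Per-(compound, day) OAV table from concentrations and the registry.

    Returns columns ``compound, group, day, conc_ppb, bdl, threshold_ppb,
    oav``; ``oav`` is NaN for threshold-less compounds and (by default) for
    BDL entries, mirroring blank cells in the study's OAV table.
    """
    t = validate_concentration_table(conc_table)
    thr: dict[str, float] = {}
    for c in compounds:
        if c.has_threshold:
            thr[c.name] = select_threshold(c.thresholds, policy)
    missing = sorted(set(t["compound"]) - set(thr))
    if missing:
        logger.warning("no odor threshold for %d compounds (OAV skipped): %s",
                       len(missing), ", ".join(missing))
    out = t[["compound", "group", "day", "conc_ppb", "bdl"]].copy()
    out["threshold_ppb"] = out["compound"].map(thr)
    eligible = out["threshold_ppb"].notna() & (include_bdl | ~out["bdl"])
    out["oav"] = float("nan")
    out.loc[eligible, "oav"] = (out.loc[eligible, "conc_ppb"]
                                / out.loc[eligible, "threshold_ppb"])
    return out


def sum_oav(oav_table: pd.DataFrame, day: int | None = None,
            group: str | None = None) -> float:
    """Sum of OAV over a scope: whole table, one day, and/or one group."""
    t = oav_table
    if day is not None:
        t = t[t["day"] == day]
    if group is not None:
        t = t[t["group"] == group]
    return float(t["oav"].dropna().sum())


def relative_proportion(oav_table: pd.DataFrame, day: int) -> pd.DataFrame:
    """RP (%) per compound for one day: 100 * OAV / that day's total OAV."""
    t = oav_table[oav_table["day"] == day]
    total = float(t["oav"].dropna().sum())
    if not total > 0:
        raise ValueError(f"day {day}: total OAV is zero; RP undefined")
    out = t.dropna(subset=["oav"]).copy()
    out["rp_percent"] = 100.0 * out["oav"] / total
    return out[["compound", "group", "day", "oav", "rp_percent"]]


def period_aggregate(oav_table: pd.DataFrame, days,
                     compounds=None) -> tuple[pd.DataFrame, float]:
    """Aggregate OAV over a storage period (a subset of sampled days).

    Returns ``(per_compound, subset_rp)``: the per-compound OAV summed over
    ``days``, and — if ``compounds`` names a subset — that subset's share
    (percent) of the all-compound OAV total over the same days.
    """
    days = set(days)
    sampled = set(oav_table["day"].unique())
    if not days <= sampled:
        raise ValueError(f"days {sorted(days - sampled)} not in sampled days "
                         f"{sorted(sampled)}")
    t = oav_table[oav_table["day"].isin(days)]
    per_compound = (t.dropna(subset=["oav"]).groupby("compound")["oav"].sum()
                    .rename("oav_sum").reset_index())
    total = float(t["oav"].dropna().sum())
    if compounds is None:
        return per_compound, 100.0 if total > 0 else math.nan
    subset_sum = float(per_compound.loc[
        per_compound["compound"].isin(set(compounds)), "oav_sum"].sum())
    subset_rp = 100.0 * subset_sum / total if total > 0 else math.nan
    return per_compound, subset_rp
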