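"""Concentration matrices across storage days and their aggregations.

Tables are long-format pandas DataFrames with one row per (compound, day):
columns ``compound, group, day, conc_ppb, conc_ugm3, bdl`` where ``bdl``
flags entries below the method detection limit.  Following the source
study's convention, a BDL entry *stores the MDL itself* as its value; an
entry counts as "detected" iff ``bdl`` is False.

Aggregations reproduce the study's summary tables: per-group detection
frequency and summed mass concentration per storage day, relative (mass)
composition (RC, % of the day's total), the major-compound filter
(RC > 0.05% on at least one day), and day-to-day detection consistency.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONC_COLUMNS",
    "validate_concentration_table",
    "apply_mdl",
    "group_sums",
    "relative_composition",
    "select_major",
    "consistency_counts",
]

CONC_COLUMNS = ("compound", "group", "day", "conc_ppb", "conc_ugm3", "bdl")


def validate_concentration_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format concentration table contract; returns a copy."""
    missing = [c for c in CONC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"concentration table missing columns {missing}")
    t = table.copy()
    t["bdl"] = t["bdl"].astype(bool)
    if (t["conc_ppb"] < 0).any() or (t["conc_ugm3"] < 0).any():
        bad = t[(t["conc_ppb"] < 0) | (t["conc_ugm3"] < 0)]
        raise ValueError(f"negative concentrations for {bad['compound'].tolist()}")
    dup = t.duplicated(subset=["compound", "day"])
    if dup.any():
        raise ValueError(f"duplicate (compound, day) rows: "
                         f"{t.loc[dup, ['compound', 'day']].values.tolist()}")
    return t


def apply_mdl(table: pd.DataFrame, mdl_ppb: dict[str, float],
              mw: dict[str, float] | None = None,
              molar_volume: float = 24.5) -> pd.DataFrame:
    """Apply method detection limits: censor sub-MDL entries.

    Entries with a measured ppbv value below their compound's MDL are flagged
    ``bdl`` and carry the MDL as their stored value (the study's reporting
    convention).  If ``mw`` is given, ``conc_ugm3`` is re-derived for
    censored entries so the dual units stay consistent.
    """
    t = validate_concentration_table(table)
    missing = sorted(set(t["compound"]) - set(mdl_ppb))
    if missing:
        raise ValueError(f"no MDL supplied for measured compounds: {missing}")
    bad = [c for c, v in mdl_ppb.items() if not v > 0]
    if bad:
        raise ValueError(f"MDL must be > 0 for {bad}")
    limits = t["compound"].map(mdl_ppb)
    censored = t["conc_ppb"] < limits
    t.loc[censored, "conc_ppb"] = limits[censored]
    t.loc[censored, "bdl"] = True
    if mw is not None:
        factor = t["compound"].map(mw) / molar_volume
        t.loc[censored, "conc_ugm3"] = t.loc[censored, "conc_ppb"] * factor[censored]
    return t


def group_sums(table: pd.DataFrame, include_bdl: bool = False) -> pd.DataFrame:
    """Per (group, day) detection counts and summed mass concentration.

    Returns columns ``group, day, n_detected, sum_ugm3``.  Detection counts
    always use ``bdl == False``; the mass sum excludes BDL placeholder values
    unless ``include_bdl`` (exclusion reproduces the study's printed sigma
    rows, where below-detection entries do not contribute).
    """
    t = validate_concentration_table(table)
    mass_src = t if include_bdl else t[~t["bdl"]]
    sums = (mass_src.groupby(["group", "day"])["conc_ugm3"].sum()
            .rename("sum_ugm3"))
    counts = (t[~t["bdl"]].groupby(["group", "day"])["compound"].nunique()
              .rename("n_detected"))
    cells = pd.MultiIndex.from_frame(
        t[["group", "day"]].drop_duplicates())  # keep all-BDL cells as zeros
    out = (pd.concat([counts, sums], axis=1).reindex(cells)
           .fillna(0.0).rename_axis(["group", "day"]).reset_index())
    out["n_detected"] = out["n_detected"].astype(int)
    return out


def relative_composition(table: pd.DataFrame,
                         total_per_day: dict[int, float]) -> pd.DataFrame:
    """Relative composition RC (%) per detected (compound, day).

    RC = 100 * conc_ugm3 / total mass concentration of the whole profile that
    day.  The denominator is the all-species total (it may exceed the table's
    own sum when the table holds only the major compounds), so the RC of the
    tabulated set sums to <= 100%.  BDL entries get no RC.
    """
    t = validate_concentration_table(table)
    bad = [d for d in t["day"].unique() if not total_per_day.get(d, 0) > 0]
    if bad:
        raise ValueError(f"total_per_day missing or non-positive for days {bad}")
    det = t[~t["bdl"]].copy()
    det["rc_percent"] = 100.0 * det["conc_ugm3"] / det["day"].map(total_per_day)
    return det[["compound", "group", "day", "conc_ugm3", "rc_percent"]]


def select_major(rc_table: pd.DataFrame, cutoff: float = 0.05) -> pd.DataFrame:
    """Compounds whose RC exceeds ``cutoff`` (%) on at least one day.

    Returns one row per qualifying compound with its peak RC and the days
    on which it qualified.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    q = rc_table[rc_table["rc_percent"] > cutoff]
    if q.empty:
        return pd.DataFrame(columns=["compound", "max_rc_percent", "qualifying_days"])
    out = (q.groupby("compound")
           .agg(max_rc_percent=("rc_percent", "max"),
                qualifying_days=("day", lambda s: tuple(sorted(s.unique()))))
           .reset_index())
    return out


def consistency_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Detected compounds also detected on the immediately preceding day.

    For each sampled day after the first, counts per group the compounds
    detected (``bdl == False``) on both that day and the previous *sampled*
    day.  Mirrors the parenthetical counts of the study's occurrence table.
    """
    t = validate_concentration_table(table)
    days = sorted(t["day"].unique())
    det = t[~t["bdl"]]
    by_day = {d: set(det.loc[det["day"] == d, "compound"]) for d in days}
    grp = det.drop_duplicates("compound").set_index("compound")["group"]
    rows = []
    for prev, day in zip(days, days[1:]):
        common = by_day[day] & by_day[prev]
        for g in sorted(det.loc[det["day"] == day, "group"].unique()):
            n = sum(1 for c in common if grp.get(c) == g)
            rows.append(dict(group=g, day=day, n_consistent=n))
    return pd.DataFrame(rows, columns=["group", "day", "n_consistent"])
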