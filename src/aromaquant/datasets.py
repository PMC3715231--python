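"""Packaged study fixtures: the strawberry storage-series tables.

These CSVs transcribe the printed summary tables of a nine-day strawberry
storage study (53 major volatiles, storage days 0/1/3/6/9).  Odor thresholds
in the registry are back-solved from printed concentration/OAV pairs (source
key ``backsolved``) because the underlying literature survey is not printed;
see ``docs/methods.md``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .registry import Compound, load_registry_csv

__all__ = [
    "load_strawberry_registry",
    "load_strawberry_concentrations",
    "load_strawberry_group_summary",
    "load_strawberry_daily_totals",
    "load_strawberry_oav_printed",
    "FRESH_DAYS",
    "DECAY_DAYS",
]

#: Storage days considered "fresh" vs. "decaying" in the study design.
FRESH_DAYS = (0, 1, 3)
DECAY_DAYS = (6, 9)


def _path(name: str):
    return resources.files(__package__) / "data" / name


def load_strawberry_registry() -> list[Compound]:
    """The 53 major volatiles: identity, moieties, thresholds, descriptors."""
    with resources.as_file(_path("strawberry_registry.csv")) as p:
        return load_registry_csv(p)


def load_strawberry_concentrations() -> pd.DataFrame:
    """Long-format dual-unit concentrations per (compound, storage day)."""
    with resources.as_file(_path("strawberry_concentrations.csv")) as p:
        return pd.read_csv(p)


def load_strawberry_group_summary() -> pd.DataFrame:
    """Whole-profile (147-species) per-group occurrence and mass sums."""
    with resources.as_file(_path("strawberry_group_summary.csv")) as p:
        return pd.read_csv(p)


def load_strawberry_daily_totals() -> dict[int, float]:
    """All-species total mass concentration (ug/m^3) per storage day."""
    with resources.as_file(_path("strawberry_daily_totals.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["day"].astype(int), df["total_ugm3"].astype(float)))


def load_strawberry_oav_printed() -> pd.DataFrame:
    """Per-compound OAV cells as printed in the source (for cross-checks)."""
    with resources.as_file(_path("strawberry_oav_printed.csv")) as p:
        return pd.read_csv(p)
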