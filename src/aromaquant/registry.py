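"""Compound registry: chemical metadata consumed by every downstream stage.

The registry is the unit of bookkeeping for a headspace-volatile study: each
compound carries its elemental formula, molecular weight, functional-group
class, the atom/moiety counts that feed the effective-carbon-number (ECN)
response model, zero or more literature odor thresholds (ppbv), and free-text
odor descriptors.  Moiety counts are *inputs* — the authoritative values come
from the registry table, not from structure perception.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GROUPS",
    "MoietyCounts",
    "ThresholdRecord",
    "Compound",
    "FormulaError",
    "RegistryError",
    "parse_formula",
    "compose_formula",
    "validate_registry",
    "load_registry_csv",
    "registry_to_frame",
]

#: The six functional classes used to organise fruit-volatile profiles.
GROUPS = ("ester", "alcohol", "aldehyde", "ketone", "fatty_acid", "etc")


class FormulaError(ValueError):
    """Malformed elemental formula."""


class RegistryError(ValueError):
    """A registry row violates a compound invariant."""


@dataclass(frozen=True)
class MoietyCounts:
    """Atom and functional-moiety counts entering the ECN score.

    ``n_carbonyl`` counts >C=O groups and ``n_ether`` counts -O- linkages;
    an ester -C(=O)-O- contributes one of each.  ``n_methyl`` counts -CH3
    groups.
    """

    n_C: int = 0
    n_H: int = 0
    n_O: int = 0
    n_carbonyl: int = 0
    n_ether: int = 0
    n_methyl: int = 0

    def __post_init__(self) -> None:
        for name in ("n_C", "n_H", "n_O", "n_carbonyl", "n_ether", "n_methyl"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise RegistryError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_carbonyl + self.n_ether > self.n_O:
            raise RegistryError(
                f"n_carbonyl + n_ether = {self.n_carbonyl + self.n_ether} "
                f"exceeds oxygen count {self.n_O}"
            )
        if 3 * self.n_methyl > self.n_H:
            raise RegistryError(
                f"{self.n_methyl} methyl groups need {3 * self.n_methyl} H "
                f"but only {self.n_H} present"
            )


@dataclass(frozen=True)
class ThresholdRecord:
    """One literature odor threshold in ppbv with its citation key."""

    value: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise RegistryError(f"odor threshold must be > 0 ppbv, got {self.value}")


@dataclass(frozen=True)
class Compound:
    """A registry entry: identity, descriptors, thresholds, calibration status."""

    name: str
    group: str
    mw: float
    formula: str = ""
    moieties: MoietyCounts | None = None
    thresholds: tuple[ThresholdRecord, ...] = ()
    descriptors: tuple[str, ...] = ()
    is_standard: bool = False
    #: elements beyond C/H/O present in the formula (ECN-ineligible if any)
    extra_elements: tuple[str, ...] = field(default=(), compare=False)

    @property
    def has_threshold(self) -> bool:
        return len(self.thresholds) > 0

    @property
    def ecn_eligible(self) -> bool:
        """ECN applies only to C/H/O compounds with known moiety counts."""
        return self.moieties is not None and not self.extra_elements


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula into atom counts.

    Returns a dict mapping element symbol to count (implicit count = 1).
    Elements other than C, H, O are returned as-is; callers decide whether
    that makes the compound ECN-ineligible.

    >>> parse_formula("C4H8O2")
    {'C': 4, 'H': 8, 'O': 2}
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected token at position {pos}"
            )
        elem, digits = m.group(1), m.group(2)
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(
            f"malformed formula {formula!r}: unexpected token at position {pos}"
        )
    return counts


def compose_formula(counts: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` for C/H/O formulas (Hill order)."""
    out = []
    for elem in ("C", "H", "O"):
        n = counts.get(elem, 0)
        if n == 1:
            out.append(elem)
        elif n > 1:
            out.append(f"{elem}{n}")
    for elem in sorted(k for k in counts if k not in ("C", "H", "O")):
        n = counts[elem]
        if n:
            out.append(elem if n == 1 else f"{elem}{n}")
    return "".join(out)


def _parse_thresholds(cell: object) -> tuple[ThresholdRecord, ...]:
    """Parse ``"0.25@ref1;10@ref2"`` (or bare values) into records."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    records = []
    for tok in str(cell).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        value, _, source = tok.partition("@")
        records.append(ThresholdRecord(float(value), source))
    return tuple(records)


def validate_registry(rows) -> list[Compound]:
    """Validate raw registry records and return :class:`Compound` objects.

    ``rows`` is an iterable of mappings (or a DataFrame) carrying at minimum
    ``name``, ``group`` and ``mw``.  Duplicate names are rejected, and when
    both a formula and moiety counts are present their C/H/O atom counts must
    agree.  Compounds without thresholds are retained (they are simply
    ineligible for odor-activity calculations).
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    compounds: list[Compound] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        name = str(row.get("name", "")).strip()
        if not name:
            raise RegistryError(f"row {i}: missing compound name")
        if name in seen:
            raise RegistryError(f"row {i}: duplicate compound name {name!r}")
        seen.add(name)
        group = str(row.get("group", "")).strip()
        if group not in GROUPS:
            raise RegistryError(
                f"row {i} ({name}): group {group!r} not one of {GROUPS}"
            )
        try:
            mw = float(row["mw"])
        except (KeyError, TypeError, ValueError):
            raise RegistryError(f"row {i} ({name}): missing or non-numeric mw") from None
        if not mw > 0:
            raise RegistryError(f"row {i} ({name}): mw must be > 0, got {mw}")

        formula = str(row.get("formula") or "").strip()
        extra: tuple[str, ...] = ()
        atom_counts: dict[str, int] = {}
        if formula:
            atom_counts = parse_formula(formula)
            extra = tuple(sorted(k for k in atom_counts if k not in ("C", "H", "O")))

        moieties = None
        if any(f"n_{k}" in row and not pd.isna(row[f"n_{k}"])
               for k in ("C", "H", "O", "carbonyl", "ether", "methyl")):
            moieties = MoietyCounts(
                n_C=int(row.get("n_C", 0) or 0),
                n_H=int(row.get("n_H", 0) or 0),
                n_O=int(row.get("n_O", 0) or 0),
                n_carbonyl=int(row.get("n_carbonyl", 0) or 0),
                n_ether=int(row.get("n_ether", 0) or 0),
                n_methyl=int(row.get("n_methyl", 0) or 0),
            )
            if atom_counts and not extra:
                for elem, attr in (("C", "n_C"), ("H", "n_H"), ("O", "n_O")):
                    if atom_counts.get(elem, 0) != getattr(moieties, attr):
                        raise RegistryError(
                            f"row {i} ({name}): formula {formula} has "
                            f"{atom_counts.get(elem, 0)} {elem} but {attr}="
                            f"{getattr(moieties, attr)}"
                        )

        desc = row.get("descriptors") or ""
        descriptors = tuple(
            d.strip() for d in str(desc).split(";") if d.strip()
        ) if not (isinstance(desc, float) and pd.isna(desc)) else ()

        compounds.append(Compound(
            name=name, group=group, mw=mw, formula=formula, moieties=moieties,
            thresholds=_parse_thresholds(row.get("thresholds")),
            descriptors=descriptors,
            is_standard=bool(row.get("is_standard", False)),
            extra_elements=extra,
        ))
    return compounds


def load_registry_csv(path) -> list[Compound]:
    """Read a registry CSV (columns per :func:`validate_registry`)."""
    return validate_registry(pd.read_csv(path))


def registry_to_frame(compounds: list[Compound]) -> pd.DataFrame:
    """Flatten compounds back into the registry CSV layout."""
    rows = []
    for c in compounds:
        m = c.moieties or MoietyCounts()
        rows.append(dict(
            name=c.name, formula=c.formula, mw=c.mw, group=c.group,
            n_C=m.n_C, n_H=m.n_H, n_O=m.n_O, n_carbonyl=m.n_carbonyl,
            n_ether=m.n_ether, n_methyl=m.n_methyl,
            thresholds=";".join(
                f"{t.value:g}@{t.source_label}" if t.source_label else f"{t.value:g}"
                for t in c.thresholds),
            descriptors=";".join(c.descriptors),
            is_standard=c.is_standard,
        ))
    return pd.DataFrame(rows)
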