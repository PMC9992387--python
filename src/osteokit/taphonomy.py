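"""Taphonomic summaries: butchery marks, burning stages, other alterations.

A record counts once per category regardless of how many individual marks
it carries; a record with both cut and percussion marks is tallied under
the combined CM+PM column only, so the three butchery columns are
mutually exclusive.  Multi-coloured burnt fragments are counted once under
their highest colouration code (0 unburned .. 5 calcined).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .quantify import unit_records
from .records import (
    CARNIVORE_MARK_KINDS,
    OTHER_MARK_KINDS,
    SpecimenRecord,
)


@dataclass
class ButcheryRow:
    label: str           # taxon or "size N" group
    nr: int              # NISP for taxa, record count for size classes
    pm: int = 0
    cm: int = 0
    cm_pm: int = 0
    retouchers: int = 0

    @property
    def pct_bm(self) -> float:
        """% butchering marks on the row's number of remains."""
        return 100.0 * (self.pm + self.cm + self.cm_pm) / self.nr if self.nr else 0.0


def _row_label(r: SpecimenRecord) -> str:
    if r.taxon:
        return r.taxon
    if r.size_class is not None:
        return f"size {r.size_class}"
    return "non-identifiable"


def butchery_summary(records: list[SpecimenRecord],
                     unit: str) -> dict[str, ButcheryRow]:
    """Per-taxon (or size-class) butchery-mark tallies for one unit."""
    rows: dict[str, ButcheryRow] = {}
    for r in unit_records(records, unit):
        label = _row_label(r)
        row = rows.setdefault(label, ButcheryRow(label, 0))
        row.nr += 1
        cut, perc = r.has_cut_marks, r.has_percussion_marks
        if cut and perc:
            row.cm_pm += 1
        elif cut:
            row.cm += 1
        elif perc:
            row.pm += 1
        if r.is_retoucher:
            row.retouchers += 1
    return rows


@dataclass
class BurnProfile:
    counts: Mapping[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, float]:
        t = self.total
        return {c: 100.0 * n / t for c, n in self.counts.items()} if t else {}

    @property
    def burned_fraction(self) -> float:
        t = self.total
        return 1.0 - self.counts.get(0, 0) / t if t else 0.0


def burn_profile(records: list[SpecimenRecord], unit: str) -> BurnProfile:
    """Histogram over burning codes 0-5; multi-code records counted once
    under their highest code."""
    counts = Counter(r.max_burn_code for r in unit_records(records, unit))
    return BurnProfile(counts=dict(sorted(counts.items())))


def modification_table(records: list[SpecimenRecord],
                       unit: str) -> dict[str, dict[str, float]]:
    """Biostratinomic/diagenetic alterations: NR and %NR per kind.

    Carnivore-damage kinds are pooled into a single "carnivore marks" row
    (kind-level counts remain available from the records themselves); the
    denominator is the unit's grand total of remains.
    """
    recs = unit_records(records, unit)
    total = len(recs)
    counts: Counter[str] = Counter()
    for r in recs:
        kinds = r.mark_kinds()
        if kinds & CARNIVORE_MARK_KINDS:
            counts["carnivore marks"] += 1
        for k in kinds & OTHER_MARK_KINDS:
            counts[k] += 1
    return {k: {"NR": n, "%NR": 100.0 * n / total}
            for k, n in sorted(counts.items())}
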