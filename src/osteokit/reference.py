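"""Published per-unit aggregates for the Fumane Protoaurignacian units.

These are the printed summary tables of the site report distilled into
machine-readable CSV: per-taxon NISP and MNI for the six determined
ungulate species (with habitat and prey-rank labels), the unit-level
ungulate age profiles, and the unit subtotals (identified NISP, MNE, MNI,
grand total of remains).  They are *inputs* for counts-mode analyses —
the specimen-level records behind them were never published.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .diet import AgeProfile

UNITS = ("A2-A1", "D3")
DETERMINED_UNGULATES = (
    "Bos/Bison sp.", "Capra ibex", "Rupicapra rupicapra",
    "Megaloceros giganteus", "Cervus elaphus", "Capreolus capreolus",
)


@dataclass(frozen=True)
class TaxonLabels:
    habitat: str
    rank: str


@dataclass
class ReferenceCounts:
    taxon_counts: pd.DataFrame       # unit, taxon, nisp, mni, habitat, rank
    age_profiles: pd.DataFrame       # unit, group, F, J, SAd, Ad, S
    unit_totals: pd.DataFrame        # unit, nisp_identified, mne, mni, grand_total

    def counts(self, unit: str, basis: str = "MNI",
               determined_only: bool = True) -> dict[str, int]:
        df = self.taxon_counts[self.taxon_counts.unit == unit]
        if determined_only:
            df = df[df.determined == 1]
        col = basis.lower()
        return dict(zip(df.taxon, df[col].astype(int)))

    def labels(self) -> dict[str, TaxonLabels]:
        return {row.taxon: TaxonLabels(row.habitat, row.rank)
                for row in self.taxon_counts.itertuples()}

    def age_profile(self, unit: str, group: str = "ungulates") -> AgeProfile:
        df = self.age_profiles[(self.age_profiles.unit == unit)
                               & (self.age_profiles.group == group)]
        row = df.iloc[0]
        return AgeProfile(F=int(row.F), J=int(row.J), SAd=int(row.SAd),
                          Ad=int(row.Ad), S=int(row.S))

    def totals(self, unit: str) -> dict[str, int]:
        df = self.unit_totals[self.unit_totals.unit == unit]
        row = df.iloc[0]
        return {k: int(row[k]) for k in
                ("nisp_identified", "mne", "mni", "grand_total")}


def _read(name: str) -> pd.DataFrame:
    with resources.files("osteokit.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def fumane_reference() -> ReferenceCounts:
    """Load the bundled counts-mode tables."""
    return ReferenceCounts(
        taxon_counts=_read("fumane_taxon_counts.csv"),
        age_profiles=_read("fumane_age_profiles.csv"),
        unit_totals=_read("fumane_unit_totals.csv"),
    )
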