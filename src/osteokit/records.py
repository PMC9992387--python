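"""Specimen-level faunal records and per-taxon skeleton templates.

The central unit of observation is the *specimen*: one bone fragment
recovered from an excavation unit, optionally identified to a taxon (or
only to a mammal body-size class 1-5), to a skeletal element and to a set
of anatomical portion codes.  Long bones and most other elements are
divided into 20 portions with unique codes; the repetition of codes and
sides across specimens is what later drives the minimum-number-of-elements
computation.

A :class:`SkeletonTemplate` carries, per taxon and element, the number of
copies in one complete skeleton, the axial/appendicular region, the maximum
bone density (used by the attrition model) and optional economic-utility
values (MGUI, FUI, CFUI, Marrow, Grease, UMI, Meat) plus per-age-class
useable meat weights.

File formats are plain CSV (UTF-8, "." decimal); multi-valued cells use
";" as the inner separator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AGE_CLASSES = ("F", "J", "SAd", "Ad", "S")
AGE_INDET = "indeterminate"
SIDES = ("left", "right", "indeterminate")
BREAKAGE = ("green", "dry", "indeterminate")
REGIONS = ("axial", "appendicular")
HABITATS = ("mountain", "plain")
RANKS = ("high", "low")
PORTION_CODES = frozenset(range(1, 21))
BURN_CODES = frozenset(range(0, 6))

CUT_MARK_KINDS = frozenset(
    {"cut_skinning", "cut_dismembering", "cut_defleshing", "scrape"}
)
PERCUSSION_MARK_KINDS = frozenset({"percussion_notch", "impact_flake"})
CARNIVORE_MARK_KINDS = frozenset(
    {"carnivore_pit", "carnivore_score", "carnivore_puncture", "furrowing",
     "digestion"}
)
OTHER_MARK_KINDS = frozenset(
    {"trampling", "root_etching", "weathering", "manganese", "concretion",
     "water_dissolution", "iron_stain"}
)
MARK_KINDS = CUT_MARK_KINDS | PERCUSSION_MARK_KINDS | CARNIVORE_MARK_KINDS | OTHER_MARK_KINDS

UTILITY_INDICES = ("MGUI", "FUI", "CFUI", "Marrow", "Grease", "UMI", "Meat")


class ValidationError(ValueError):
    """A record or template row violates a domain invariant."""


@dataclass(frozen=True)
class Mark:
    """One kind of surface modification with its occurrence count."""

    kind: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.kind not in MARK_KINDS:
            raise ValidationError(f"unknown mark kind {self.kind!r}")
        if self.count < 1:
            raise ValidationError(f"mark count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One bone fragment with its taxonomic, anatomical and taphonomic data.

    A record is identified either to a taxon *or* to a body-size class
    (1-5), never meaningfully to both; carrying both at once is rejected.
    ``burn_code`` is a tuple because a single fragment can show several
    burning colourations; summaries count such records once under their
    highest code.
    """

    record_id: str
    unit: str
    square: str = ""
    taxon: str = ""
    size_class: int | None = None
    element: str = ""
    portion_codes: frozenset[int] = frozenset()
    side: str = "indeterminate"
    age_class: str = AGE_INDET
    surface_mods: tuple[Mark, ...] = ()
    burn_code: tuple[int, ...] = (0,)
    breakage: str = "indeterminate"
    is_retoucher: bool = False

    def __post_init__(self) -> None:
        if self.taxon and self.size_class is not None:
            raise ValidationError(
                f"record {self.record_id}: taxon and size_class are mutually "
                "exclusive identifications"
            )
        if self.size_class is not None and not 1 <= self.size_class <= 5:
            raise ValidationError(
                f"record {self.record_id}: size_class must be 1-5"
            )
        if not self.portion_codes <= PORTION_CODES:
            bad = sorted(set(self.portion_codes) - PORTION_CODES)
            raise ValidationError(
                f"record {self.record_id}: portion_codes outside 1-20: {bad}"
            )
        if self.portion_codes and not self.element:
            raise ValidationError(
                f"record {self.record_id}: portion codes given without element"
            )
        if self.side not in SIDES:
            raise ValidationError(
                f"record {self.record_id}: side must be one of {SIDES}"
            )
        if self.age_class not in AGE_CLASSES and self.age_class != AGE_INDET:
            raise ValidationError(
                f"record {self.record_id}: age_class {self.age_class!r} not in "
                f"{AGE_CLASSES + (AGE_INDET,)}"
            )
        if not set(self.burn_code) <= BURN_CODES:
            bad = sorted(set(self.burn_code) - BURN_CODES)
            raise ValidationError(
                f"record {self.record_id}: burn_code outside 0-5: {bad}"
            )
        if not self.burn_code:
            raise ValidationError(f"record {self.record_id}: empty burn_code")
        if self.breakage not in BREAKAGE:
            raise ValidationError(
                f"record {self.record_id}: breakage must be one of {BREAKAGE}"
            )

    @property
    def is_identified(self) -> bool:
        """True when the record is determined to a taxon."""
        return bool(self.taxon)

    @property
    def max_burn_code(self) -> int:
        return max(self.burn_code)

    def mark_kinds(self) -> set[str]:
        return {m.kind for m in self.surface_mods}

    @property
    def has_cut_marks(self) -> bool:
        return bool(self.mark_kinds() & CUT_MARK_KINDS)

    @property
    def has_percussion_marks(self) -> bool:
        return bool(self.mark_kinds() & PERCUSSION_MARK_KINDS)

    @property
    def has_carnivore_marks(self) -> bool:
        return bool(self.mark_kinds() & CARNIVORE_MARK_KINDS)


@dataclass(frozen=True)
class TemplateElement:
    """One skeletal element of a taxon's complete skeleton."""

    element: str
    skeleton_count: int
    region: str
    density: float
    utility: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.skeleton_count < 1:
            raise ValidationError(
                f"element {self.element}: skeleton_count must be >= 1"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"element {self.element}: region must be one of {REGIONS}"
            )
        if not 0.0 < self.density <= 1.0:
            raise ValidationError(
                f"element {self.element}: density must be in (0, 1], "
                f"got {self.density}"
            )
        for k in self.utility:
            if k not in UTILITY_INDICES:
                raise ValidationError(
                    f"element {self.element}: unknown utility index {k!r}"
                )


@dataclass(frozen=True)
class SkeletonTemplate:
    """Element inventory of one taxon, with habitat and prey-rank labels."""

    taxon: str
    elements: tuple[TemplateElement, ...]
    habitat: str = "mountain"
    rank: str = "high"
    # useable meat per individual, by age class (kg); taxon-level because
    # biomass is computed per individual, not per element
    meat_weight_kg: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, w in self.meat_weight_kg.items():
            if a not in AGE_CLASSES:
                raise ValidationError(f"unknown age class {a!r} in meat weights")
            if w < 0:
                raise ValidationError(f"negative meat weight for {a!r}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"habitat must be one of {HABITATS}")
        if self.rank not in RANKS:
            raise ValidationError(f"rank must be one of {RANKS}")
        seen: set[str] = set()
        for e in self.elements:
            if e.element in seen:
                raise ValidationError(
                    f"duplicate element {e.element!r} for taxon {self.taxon!r}"
                )
            seen.add(e.element)

    def element_names(self) -> tuple[str, ...]:
        return tuple(e.element for e in self.elements)

    def __getitem__(self, element: str) -> TemplateElement:
        for e in self.elements:
            if e.element == element:
                return e
        raise KeyError(element)

    def __contains__(self, element: str) -> bool:
        return any(e.element == element for e in self.elements)


# ---------------------------------------------------------------------------
# CSV serialisation

SPECIMEN_COLUMNS = [
    "record_id", "unit", "square", "taxon", "size_class", "element",
    "portion_codes", "side", "age_class", "surface_mods", "burn_code",
    "breakage", "is_retoucher",
]

TEMPLATE_COLUMNS = (
    ["taxon", "element", "skeleton_count", "region", "density"]
    + ["MGUI", "FUI", "CFUI", "Marrow", "Grease", "UMI"]
    + [f"meat_{a}" for a in AGE_CLASSES]
    + ["habitat", "rank"]
)

_LIST_SEP = ";"


def _fmt_marks(marks: Sequence[Mark]) -> str:
    return _LIST_SEP.join(f"{m.kind}:{m.count}" for m in marks)


def _parse_marks(cell: str, row: int) -> tuple[Mark, ...]:
    if not cell.strip():
        return ()
    marks = []
    for part in cell.split(_LIST_SEP):
        part = part.strip()
        if not part:
            continue
        kind, _, cnt = part.partition(":")
        if kind not in MARK_KINDS:
            raise ValidationError(
                f"row {row}: field surface_mods: unknown mark kind {kind!r}"
            )
        marks.append(Mark(kind, int(cnt) if cnt else 1))
    return tuple(marks)


def _parse_int_list(cell: str) -> tuple[int, ...]:
    return tuple(int(p) for p in cell.split(_LIST_SEP) if p.strip())


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Read specimen records from CSV, preserving file order.

    Every row is validated; the first invalid row raises a
    :class:`ValidationError` naming the 1-based data row and the offending
    field.
    """
    records: list[SpecimenRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(SPECIMEN_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    SpecimenRecord(
                        record_id=row["record_id"].strip(),
                        unit=row["unit"].strip(),
                        square=row["square"].strip(),
                        taxon=row["taxon"].strip(),
                        size_class=(int(row["size_class"])
                                    if row["size_class"].strip() else None),
                        element=row["element"].strip(),
                        portion_codes=frozenset(
                            _parse_int_list(row["portion_codes"])),
                        side=row["side"].strip() or "indeterminate",
                        age_class=row["age_class"].strip() or AGE_INDET,
                        surface_mods=_parse_marks(row["surface_mods"], i),
                        burn_code=_parse_int_list(row["burn_code"]) or (0,),
                        breakage=row["breakage"].strip() or "indeterminate",
                        is_retoucher=row["is_retoucher"].strip().lower()
                        in ("1", "true", "yes"),
                    )
                )
            except ValidationError:
                raise
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_specimens(records: Iterable[SpecimenRecord],
                    path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPECIMEN_COLUMNS)
        for r in records:
            writer.writerow([
                r.record_id, r.unit, r.square, r.taxon,
                "" if r.size_class is None else r.size_class,
                r.element,
                _LIST_SEP.join(str(c) for c in sorted(r.portion_codes)),
                r.side, r.age_class, _fmt_marks(r.surface_mods),
                _LIST_SEP.join(str(c) for c in r.burn_code),
                r.breakage, "1" if r.is_retoucher else "0",
            ])


def read_template(path: str | Path) -> dict[str, SkeletonTemplate]:
    """Read skeleton templates (one row per taxon x element) from CSV.

    Returns a mapping taxon -> :class:`SkeletonTemplate`.  Missing utility
    values are allowed and simply absent from the element's mapping.
    """
    by_taxon: dict[str, list[TemplateElement]] = {}
    labels: dict[str, tuple[str, str, dict[str, float]]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=1):
            taxon = row["taxon"].strip()
            element = row["element"].strip()
            if (taxon, element) in seen:
                raise ValidationError(
                    f"row {i}: duplicate taxon x element {taxon!r} x "
                    f"{element!r}"
                )
            seen.add((taxon, element))
            utility = {}
            for idx in ("MGUI", "FUI", "CFUI", "Marrow", "Grease", "UMI"):
                cell = row.get(idx, "").strip()
                if cell:
                    utility[idx] = float(cell)
            meat = {}
            for a in AGE_CLASSES:
                cell = (row.get(f"meat_{a}") or "").strip()
                if cell:
                    meat[a] = float(cell)
            try:
                elem = TemplateElement(
                    element=element,
                    skeleton_count=int(row["skeleton_count"]),
                    region=row["region"].strip(),
                    density=float(row["density"]),
                    utility=utility,
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            by_taxon.setdefault(taxon, []).append(elem)
            if taxon not in labels:
                labels[taxon] = ((row.get("habitat") or "mountain").strip(),
                                 (row.get("rank") or "high").strip(), meat)
    out = {}
    for taxon, elems in by_taxon.items():
        habitat, rank, meat = labels[taxon]
        out[taxon] = SkeletonTemplate(
            taxon=taxon, elements=tuple(elems), habitat=habitat, rank=rank,
            meat_weight_kg=meat,
        )
    return out


def write_template(templates: Mapping[str, SkeletonTemplate],
                   path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TEMPLATE_COLUMNS)
        for taxon in templates:
            t = templates[taxon]
            for j, e in enumerate(t.elements):
                row = [taxon, e.element, e.skeleton_count, e.region,
                       repr(e.density)]
                for idx in ("MGUI", "FUI", "CFUI", "Marrow", "Grease", "UMI"):
                    row.append("" if idx not in e.utility
                               else repr(e.utility[idx]))
                for a in AGE_CLASSES:
                    v = t.meat_weight_kg.get(a) if j == 0 else None
                    row.append("" if v is None else repr(v))
                row += [t.habitat, t.rank]
                writer.writerow(row)


def ages_compatible(a: str, b: str) -> bool:
    """Two age classes can belong to the same element/individual."""
    return a == AGE_INDET or b == AGE_INDET or a == b


def sides_compatible(a: str, b: str) -> bool:
    return a == "indeterminate" or b == "indeterminate" or a == b
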