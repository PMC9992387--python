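"""Assemblage quantification: NISP, MNE, MNI, MAU and %MAU.

MNE is defined here as the *minimum number of whole skeletal elements
consistent with the observed fragments*: two fragments can derive from the
same element only if their portion codes are disjoint, their sides are
compatible (left/right/indeterminate) and their age classes are compatible
(the five determinate classes are mutually exclusive; indeterminate matches
anything).  The computation is an exact minimum-partition search
(branch-and-bound over assignments of fragments to hypothetical elements),
not the classical max-repetition shortcut, because overlapping fragment
triples can force more elements than any single portion code is repeated.

MNI follows from the per-element decomposition: for paired elements the
left/right instances are matched under age compatibility (maximum-cardinality
matching), and the minimum number of individuals is instances minus matched
pairs; for elements occurring k times per skeleton the bound
max(ceil(N/k), sum_a ceil(n_a/k)) over age classes a is exact.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .records import (
    AGE_CLASSES,
    AGE_INDET,
    SkeletonTemplate,
    SpecimenRecord,
    ages_compatible,
    sides_compatible,
)

log = logging.getLogger("osteokit")


class QuantificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NISP


def available_units(records: list[SpecimenRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.unit, None)
    return list(seen)


def unit_records(records: list[SpecimenRecord],
                 unit: str) -> list[SpecimenRecord]:
    units = available_units(records)
    if unit not in units:
        raise QuantificationError(
            f"unknown unit {unit!r}; available units: {units}")
    return [r for r in records if r.unit == unit]


def compute_nisp(records: list[SpecimenRecord],
                 unit: str) -> dict[str, dict[str, float]]:
    """Per-taxon NISP and %NISP for one unit.

    Only taxon-identified records count toward NISP; records identified
    only to a body-size class are excluded.  %NISP uses the unit's
    identified subtotal as denominator.
    """
    recs = unit_records(records, unit)
    counts = Counter(r.taxon for r in recs if r.is_identified)
    total = sum(counts.values())
    out = {}
    for taxon, n in counts.items():
        out[taxon] = {"NISP": n, "%NISP": 100.0 * n / total}
    log.info("unit %s: NISP over %d identified of %d records",
             unit, total, len(recs))
    return out


# ---------------------------------------------------------------------------
# MNE: exact minimum-element partition


@dataclass
class ElementInstance:
    """One hypothetical whole element reconstructed from fragments."""

    side: str = "indeterminate"
    age: str = AGE_INDET
    codes: set[int] = field(default_factory=set)
    n_fragments: int = 0

    def accepts(self, frag: SpecimenRecord) -> bool:
        return (not (self.codes & frag.portion_codes)
                and sides_compatible(self.side, frag.side)
                and ages_compatible(self.age, frag.age_class))

    def add(self, frag: SpecimenRecord) -> None:
        self.codes |= frag.portion_codes
        if frag.side != "indeterminate":
            self.side = frag.side
        if frag.age_class != AGE_INDET:
            self.age = frag.age_class
        self.n_fragments += 1


def _labels_compatible(a: SpecimenRecord, b: SpecimenRecord) -> bool:
    return (sides_compatible(a.side, b.side)
            and ages_compatible(a.age_class, b.age_class))


def _components(frags: list[SpecimenRecord]) -> list[list[SpecimenRecord]]:
    """Connected components of the label-compatibility relation.

    Fragments in different components can never share an element, so each
    component is an independent minimisation problem.
    """
    n = len(frags)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _labels_compatible(frags[i], frags[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[SpecimenRecord]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(frags[i])
    return list(comps.values())


def _greedy_partition(frags: list[SpecimenRecord]) -> list[ElementInstance]:
    """First-fit-decreasing assignment; an upper bound on the minimum."""
    groups: list[ElementInstance] = []
    for f in sorted(frags, key=lambda f: -len(f.portion_codes)):
        for g in groups:
            if g.accepts(f):
                g.add(f)
                break
        else:
            g = ElementInstance()
            g.add(f)
            groups.append(g)
    return groups


def _code_lower_bound(frags: list[SpecimenRecord]) -> int:
    """Fragments sharing any portion code must lie in distinct elements."""
    if not frags:
        return 0
    mult = Counter(c for f in frags for c in f.portion_codes)
    return max(mult.values(), default=1)


_MAX_NODES = 500_000


def _min_partition(frags: list[SpecimenRecord]) -> list[ElementInstance]:
    """Exact minimum partition of fragments into consistent elements.

    Branch and bound with empty-group symmetry reduction.  Falls back to
    the greedy solution (with a warning) if the search exceeds its node
    budget, which does not occur at realistic per-element fragment counts.
    """
    if not frags:
        return []
    greedy = _greedy_partition(frags)
    lb = _code_lower_bound(frags)
    if len(greedy) == lb:
        return greedy

    order = sorted(frags, key=lambda f: -len(f.portion_codes))
    best_groups = [(g.side, g.age, frozenset(g.codes), g.n_fragments)
                   for g in greedy]
    best = len(greedy)
    nodes = 0
    exhausted = False

    def dfs(i: int, groups: list[ElementInstance]) -> None:
        nonlocal best, best_groups, nodes, exhausted
        nodes += 1
        if nodes > _MAX_NODES:
            exhausted = True
            return
        if len(groups) >= best:
            return
        if i == len(order):
            best = len(groups)
            best_groups = [(g.side, g.age, frozenset(g.codes), g.n_fragments)
                           for g in groups]
            return
        f = order[i]
        for g in groups:
            if g.accepts(f):
                saved = (g.side, g.age, set(g.codes), g.n_fragments)
                g.add(f)
                dfs(i + 1, groups)
                g.side, g.age, g.codes, g.n_fragments = saved
                if exhausted:
                    return
        g = ElementInstance()
        g.add(f)
        groups.append(g)
        dfs(i + 1, groups)
        groups.pop()

    dfs(0, [])
    if exhausted:
        log.warning("MNE search truncated at %d nodes; greedy bound used",
                    _MAX_NODES)
    out = []
    for side, age, codes, nf in best_groups:
        g = ElementInstance(side=side, age=age, codes=set(codes))
        g.n_fragments = nf
        out.append(g)
    return out


def mne_decomposition(records: list[SpecimenRecord], taxon: str,
                      element: str) -> list[ElementInstance]:
    """Reconstructed element instances (with side/age) for taxon x element."""
    frags = [r for r in records
             if r.taxon == taxon and r.element == element]
    for f in frags:
        if f.portion_codes and not f.element:
            raise QuantificationError(
                f"record {f.record_id}: portion codes without element")
    instances: list[ElementInstance] = []
    for comp in _components(frags):
        instances.extend(_min_partition(comp))
    return instances


def compute_mne(records: list[SpecimenRecord], taxon: str,
                element: str) -> int:
    """Minimum number of whole elements consistent with the fragments."""
    return len(mne_decomposition(records, taxon, element))


def elements_of(records: list[SpecimenRecord], taxon: str) -> list[str]:
    seen: dict[str, None] = {}
    for r in records:
        if r.taxon == taxon and r.element:
            seen.setdefault(r.element, None)
    return list(seen)


def mne_by_element(records: list[SpecimenRecord],
                   taxon: str) -> dict[str, int]:
    return {e: compute_mne(records, taxon, e)
            for e in elements_of(records, taxon)}


# ---------------------------------------------------------------------------
# MNI


def _min_individuals_paired(instances: list[ElementInstance]) -> list[str]:
    """Minimum individuals for a paired (2-per-skeleton) element.

    Two instances can belong to the same individual iff their sides are
    not the same determinate side and their ages are compatible.  The
    minimum number of individuals is then N minus a maximum-cardinality
    matching.  Returns the per-individual age labels.
    """
    n = len(instances)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = instances[i], instances[j]
            same_det_side = (a.side == b.side and a.side != "indeterminate")
            if not same_det_side and ages_compatible(a.age, b.age):
                g.add_edge(i, j)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    used = set()
    ages = []
    for i, j in matching:
        used |= {i, j}
        det = [x.age for x in (instances[i], instances[j])
               if x.age != AGE_INDET]
        ages.append(det[0] if det else AGE_INDET)
    for i in range(n):
        if i not in used:
            ages.append(instances[i].age)
    return ages


def _min_individuals_pooled(instances: list[ElementInstance],
                            k: int) -> list[str]:
    """Minimum individuals for an element occurring k times per skeleton.

    Sides are ignored (vertebrae, phalanx pools etc.); per determinate age
    class a with n_a instances at least ceil(n_a / k) individuals are
    needed, and indeterminate-age instances fill leftover capacity before
    forcing new individuals.
    """
    by_age = Counter(inst.age for inst in instances)
    n_ind = by_age.pop(AGE_INDET, 0)
    ages: list[str] = []
    capacity = 0
    for a, n in by_age.items():
        m = math.ceil(n / k)
        ages.extend([a] * m)
        capacity += m * k - n
    extra = max(0, math.ceil((n_ind - capacity) / k))
    ages.extend([AGE_INDET] * extra)
    return ages


def mni_for_element(records: list[SpecimenRecord], taxon: str, element: str,
                    template: SkeletonTemplate) -> list[str]:
    """Per-individual age labels implied by one element's instances."""
    if element not in template:
        raise QuantificationError(
            f"element {element!r} absent from template for {taxon!r}")
    instances = mne_decomposition(records, taxon, element)
    k = template[element].skeleton_count
    if k == 2:
        return _min_individuals_paired(instances)
    return _min_individuals_pooled(instances, k)


def compute_mni(records: list[SpecimenRecord], taxon: str,
                template: SkeletonTemplate) -> tuple[int, dict[str, int]]:
    """MNI with its per-age-class breakdown.

    The MNI is the maximum over elements of the minimum individuals each
    element implies; the breakdown comes from the element attaining the
    maximum (ties broken by template order).
    """
    best_ages: list[str] = []
    order = {e: i for i, e in enumerate(template.element_names())}
    for element in sorted(elements_of(records, taxon),
                          key=lambda e: order.get(e, len(order))):
        ages = mni_for_element(records, taxon, element, template)
        if len(ages) > len(best_ages):
            best_ages = ages
    breakdown = {a: 0 for a in AGE_CLASSES}
    breakdown[AGE_INDET] = 0
    for a in best_ages:
        breakdown[a] += 1
    return len(best_ages), breakdown


# ---------------------------------------------------------------------------
# MAU


def compute_mau(mne: dict[str, int],
                template: SkeletonTemplate) -> tuple[dict[str, float],
                                                     dict[str, float]]:
    """MAU = MNE / skeleton_count; %MAU normalised to the maximum MAU."""
    mau = {}
    for element, n in mne.items():
        if element not in template:
            raise QuantificationError(
                f"element {element!r} absent from template for "
                f"{template.taxon!r}")
        mau[element] = n / template[element].skeleton_count
    top = max(mau.values(), default=0.0)
    pct = {e: (100.0 * v / top if top > 0 else 0.0) for e, v in mau.items()}
    return mau, pct


# ---------------------------------------------------------------------------
# Brute-force oracles (exhaustive search, used by the test suite)


def mne_bruteforce(frags: list[SpecimenRecord]) -> int:
    """Exhaustive minimum over all assignments of fragments to elements."""
    best = len(frags) if frags else 0

    def rec(i: int, groups: list[ElementInstance]) -> None:
        nonlocal best
        if i == len(frags):
            best = min(best, len(groups))
            return
        if len(groups) >= best:
            return
        f = frags[i]
        for g in groups:
            if g.accepts(f):
                saved = (g.side, g.age, set(g.codes), g.n_fragments)
                g.add(f)
                rec(i + 1, groups)
                g.side, g.age, g.codes, g.n_fragments = saved
        g = ElementInstance()
        g.add(f)
        groups.append(g)
        rec(i + 1, groups)
        groups.pop()

    if frags:
        rec(0, [])
    return best


def mni_bruteforce(instances: list[ElementInstance], k: int) -> int:
    """Exhaustive minimum individuals for one element type.

    An individual holds at most k instances; for k == 2 at most one left
    and one right; all instances of an individual must have compatible
    ages (and, pairwise, compatible sides).
    """
    best = len(instances) if instances else 0

    def fits(group: list[ElementInstance], inst: ElementInstance) -> bool:
        if len(group) >= k:
            return False
        for other in group:
            if not ages_compatible(other.age, inst.age):
                return False
        if k == 2 and group:
            other = group[0]
            if (other.side == inst.side and other.side != "indeterminate"):
                return False
        return True

    def rec(i: int, groups: list[list[ElementInstance]]) -> None:
        nonlocal best
        if i == len(instances):
            best = min(best, len(groups))
            return
        if len(groups) >= best:
            return
        inst = instances[i]
        for g in groups:
            if fits(g, inst):
                g.append(inst)
                rec(i + 1, groups)
                g.pop()
        groups.append([inst])
        rec(i + 1, groups)
        groups.pop()

    if instances:
        rec(0, [])
    return best
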