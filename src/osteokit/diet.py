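"""Diet breadth, prey selection, biomass and mortality-profile statistics.

Diet breadth is measured with the inverse Simpson index 1/D where
D = sum p_i^2 and p_i are taxon proportions (of NISP or MNI); the higher
the value, the broader the diet.  Prey-selection ratios compare mountain
versus plain habitat taxa (hunting preference) or high- versus low-ranked
prey.  Mortality profiles group the five age classes into juveniles
(F + J + SAd), prime adults (Ad) and old (S) for ternary plotting, and the
juvenile/adult ratio is (F + J + SAd) / (Ad + S).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .records import AGE_CLASSES, SkeletonTemplate


class DietStatsError(ValueError):
    pass


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero, matching how the source tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiversityResult:
    basis: str
    counts: Mapping[str, int]
    inverse_simpson: float


def inverse_simpson(counts: Mapping[str, int] | list[int]) -> float:
    """Inverse Simpson diversity 1/D with D = sum (n_i / N)^2.

    Bounded between 1 (one taxon dominates completely) and the number of
    taxa with nonzero counts (perfect evenness).
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if any(v < 0 for v in values):
        raise DietStatsError("counts must be nonnegative")
    total = sum(values)
    if total == 0:
        raise DietStatsError("all counts are zero; diversity undefined")
    d = sum((v / total) ** 2 for v in values)
    return 1.0 / d


@dataclass(frozen=True)
class AgeProfile:
    """Counts of individuals per age class F/J/SAd/Ad/S."""

    F: int = 0
    J: int = 0
    SAd: int = 0
    Ad: int = 0
    S: int = 0

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AgeProfile":
        return cls(**{a: int(counts.get(a, 0)) for a in AGE_CLASSES})

    @property
    def total(self) -> int:
        return self.F + self.J + self.SAd + self.Ad + self.S

    @property
    def juveniles(self) -> int:
        return self.F + self.J + self.SAd

    @property
    def adults(self) -> int:
        return self.Ad + self.S


def juvenile_adult_ratio(profile: AgeProfile) -> float:
    """(F + J + SAd) / (Ad + S): pressure on low-return younger prey."""
    if profile.adults == 0:
        raise DietStatsError("no adult individuals; ratio undefined")
    return profile.juveniles / profile.adults


def prime_age_share(profile: AgeProfile) -> float:
    """Percentage of adult + senile individuals in the profile."""
    if profile.total == 0:
        raise DietStatsError("empty age profile")
    return 100.0 * profile.adults / profile.total


def ternary_coordinates(profile: AgeProfile) -> tuple[float, float, float]:
    """(juvenile, prime, old) proportions for the mortality triangle.

    Species with four or fewer individuals are conventionally excluded
    from the plot; see :func:`ternary_point`.
    """
    if profile.total == 0:
        raise DietStatsError("empty age profile")
    t = profile.total
    return (profile.juveniles / t, profile.Ad / t, profile.S / t)


def ternary_point(profile: AgeProfile) -> dict:
    j, p, o = ternary_coordinates(profile)
    return {"juvenile": j, "prime": p, "old": o,
            "excluded_from_plot": profile.total <= 4}


def prey_ratio(counts: Mapping[str, int],
               templates: Mapping[str, SkeletonTemplate],
               attribute: str = "habitat") -> float:
    """Ratio of group-A to group-B counts for a binary taxon attribute.

    ``attribute="habitat"`` gives mountain / plain (hunting preference);
    ``attribute="rank"`` gives high- / low-ranked prey.  Taxa absent from
    ``templates`` are ignored.
    """
    if attribute == "habitat":
        groups = ("mountain", "plain")
    elif attribute == "rank":
        groups = ("high", "low")
    else:
        raise DietStatsError(f"unknown attribute {attribute!r}")
    a = sum(n for t, n in counts.items()
            if t in templates and getattr(templates[t], attribute) == groups[0])
    b = sum(n for t, n in counts.items()
            if t in templates and getattr(templates[t], attribute) == groups[1])
    if b == 0:
        raise DietStatsError(f"no counts in {groups[1]!r} group; ratio undefined")
    return a / b


def group_share(counts: Mapping[str, int],
                templates: Mapping[str, SkeletonTemplate],
                attribute: str = "habitat",
                group: str = "mountain") -> float:
    """Percentage of counts in one attribute group, over classified taxa."""
    total = sum(n for t, n in counts.items() if t in templates)
    if total == 0:
        raise DietStatsError("no classified counts")
    part = sum(n for t, n in counts.items()
               if t in templates and getattr(templates[t], attribute) == group)
    return 100.0 * part / total


def biomass(mni_by_age: Mapping[str, int],
            template: SkeletonTemplate) -> float:
    """Useable meat in kg: sum over ages of MNI(age) x meat weight(age)."""
    total = 0.0
    missing = []
    for age, n in mni_by_age.items():
        if n == 0 or age not in AGE_CLASSES:
            continue
        if age not in template.meat_weight_kg:
            missing.append(f"{template.taxon} x {age}")
            continue
        total += n * template.meat_weight_kg[age]
    if missing:
        raise DietStatsError(
            "missing meat weight for: " + ", ".join(missing))
    return total
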