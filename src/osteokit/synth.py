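"""Synthetic assemblages, DEMs and NPP series with known ground truth.

The assemblage generator simulates the formation history that the
analytical stages assume: complete skeletons of each simulated individual
pass through a transport filter (element retained with probability
proportional to its region's transport weight at the true alpha), then
through density-mediated attrition (survival d**beta), and each surviving
element is finally broken into fragments carrying contiguous runs of the
20 anatomical portion codes.  Butchery, carnivore and burning
modifications are applied at configurable per-fragment rates.  A ground
truth ledger records everything a recovery experiment needs.

All randomness descends from a single integer seed via numpy's seed
sequence spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bayes import transport_weight
from .catchment import DEMRaster
from .nppstats import NPPSeries
from .records import AGE_CLASSES, Mark, SkeletonTemplate, SpecimenRecord

_N_PORTIONS = 20


class ScenarioError(ValueError):
    pass


@dataclass
class TaxonScenario:
    n_individuals: int
    age_probs: Mapping[str, float] = field(
        default_factory=lambda: {"J": 0.25, "SAd": 0.1, "Ad": 0.55, "S": 0.1})

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ScenarioError("n_individuals must be >= 0")
        s = sum(self.age_probs.values())
        if not np.isclose(s, 1.0):
            raise ScenarioError(f"age probabilities sum to {s}, expected 1")
        for a in self.age_probs:
            if a not in AGE_CLASSES:
                raise ScenarioError(f"unknown age class {a!r}")


@dataclass
class AssemblageScenario:
    """True formation parameters for one synthetic unit."""

    unit: str
    taxa: Mapping[str, TaxonScenario]
    alpha: float = 0.0
    beta: float = 0.0
    fragmentation: float = 1.0       # mean fragments per surviving element
    cut_mark_rate: float = 0.0       # per fragment
    percussion_mark_rate: float = 0.0
    carnivore_mark_rate: float = 0.0
    burn_probs: Sequence[float] = (1.0, 0, 0, 0, 0, 0)  # over codes 0..5
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.alpha <= 1.0:
            raise ScenarioError("alpha must be in [-1, 1]")
        if self.beta < 0:
            raise ScenarioError("beta must be >= 0")
        if self.fragmentation < 1.0:
            raise ScenarioError("fragmentation intensity must be >= 1")
        for p in (self.cut_mark_rate, self.percussion_mark_rate,
                  self.carnivore_mark_rate):
            if not 0.0 <= p <= 1.0:
                raise ScenarioError("mark rates must be probabilities")
        if len(self.burn_probs) != 6 or not np.isclose(sum(self.burn_probs),
                                                       1.0):
            raise ScenarioError("burn_probs must be 6 probabilities summing "
                                "to 1")


def _fragment_codes(rng: np.random.Generator,
                    intensity: float) -> list[frozenset[int]]:
    """Split portion codes 1..20 into contiguous runs.

    The number of fragments is 1 + Poisson(intensity - 1), capped at 20.
    """
    nf = min(_N_PORTIONS, 1 + rng.poisson(max(0.0, intensity - 1.0)))
    if nf == 1:
        return [frozenset(range(1, _N_PORTIONS + 1))]
    cuts = np.sort(rng.choice(np.arange(1, _N_PORTIONS), size=nf - 1,
                              replace=False))
    bounds = [0, *cuts.tolist(), _N_PORTIONS]
    return [frozenset(range(bounds[i] + 1, bounds[i + 1] + 1))
            for i in range(nf)]


def generate_assemblage(
        scenario: AssemblageScenario,
        templates: Mapping[str, SkeletonTemplate],
) -> tuple[list[SpecimenRecord], dict]:
    """Simulate specimen records plus a ground-truth ledger.

    At alpha = 0, beta = 0 and fragmentation 1 the output is lossless:
    every element of every individual appears exactly once, unbroken.
    """
    root = np.random.SeedSequence(scenario.seed)
    records: list[SpecimenRecord] = []
    truth: dict = {
        "alpha": scenario.alpha, "beta": scenario.beta,
        "seed": scenario.seed, "n_individuals": {}, "ages": {},
        "element_survival": {},
    }
    max_w = max(transport_weight("axial", scenario.alpha),
                transport_weight("appendicular", scenario.alpha))
    rid = 0
    for taxon, tax_seed in zip(scenario.taxa,
                               root.spawn(len(scenario.taxa))):
        rng = np.random.default_rng(tax_seed)
        spec = scenario.taxa[taxon]
        template = templates[taxon]
        truth["n_individuals"][taxon] = spec.n_individuals
        ages = rng.choice(list(spec.age_probs), size=spec.n_individuals,
                          p=list(spec.age_probs.values()))
        truth["ages"][taxon] = [str(a) for a in ages]
        survival: dict[str, int] = {e.element: 0 for e in template.elements}
        for ind in range(spec.n_individuals):
            age = str(ages[ind])
            for elem in template.elements:
                k = elem.skeleton_count
                sides = (["left", "right"] if k == 2
                         else ["indeterminate"] * k)
                p_keep = (transport_weight(elem.region, scenario.alpha)
                          / max_w)
                p_surv = elem.density ** scenario.beta
                for side in sides:
                    if rng.random() > p_keep:
                        continue
                    if rng.random() > p_surv:
                        continue
                    survival[elem.element] += 1
                    for codes in _fragment_codes(rng,
                                                 scenario.fragmentation):
                        rid += 1
                        marks = []
                        if rng.random() < scenario.cut_mark_rate:
                            marks.append(Mark("cut_defleshing"))
                        if rng.random() < scenario.percussion_mark_rate:
                            marks.append(Mark("percussion_notch"))
                        if rng.random() < scenario.carnivore_mark_rate:
                            marks.append(Mark("carnivore_score"))
                        burn = int(rng.choice(6, p=scenario.burn_probs))
                        records.append(SpecimenRecord(
                            record_id=f"{scenario.unit}-{rid:06d}",
                            unit=scenario.unit,
                            taxon=taxon,
                            element=elem.element,
                            portion_codes=codes,
                            side=side,
                            age_class=age,
                            surface_mods=tuple(marks),
                            burn_code=(burn,),
                        ))
        truth["element_survival"][taxon] = survival
    return records, truth


def caprine_template(n_elements: int = 20, seed: int = 7,
                     taxon: str = "synthetic caprine",
                     habitat: str = "mountain",
                     rank: str = "high") -> SkeletonTemplate:
    """A synthetic caprine-like skeleton template.

    Element densities span (0.2, 0.95], appendicular elements are denser
    on average (as in real skeletons, where limb shafts outlast vertebrae),
    and skeleton counts mix paired limb bones with axial pools.
    """
    from .records import TemplateElement

    rng = np.random.default_rng(seed)
    elements = []
    for i in range(n_elements):
        appendicular = i % 2 == 0
        dens = float(rng.uniform(0.45 if appendicular else 0.2,
                                 0.95 if appendicular else 0.7))
        if appendicular:
            k = 2
        else:
            k = int(rng.choice([1, 6, 12], p=[0.5, 0.3, 0.2]))
        elements.append(TemplateElement(
            element=f"element_{i:02d}",
            skeleton_count=k,
            region="appendicular" if appendicular else "axial",
            density=round(dens, 3),
        ))
    return SkeletonTemplate(
        taxon=taxon, elements=tuple(elements), habitat=habitat, rank=rank,
        meat_weight_kg={"F": 2.0, "J": 10.0, "SAd": 18.0, "Ad": 25.0,
                        "S": 22.0},
    )


def generate_dem(kind: str, shape: tuple[int, int] = (100, 100),
                 cell_size: float = 100.0, seed: int = 0,
                 **params) -> DEMRaster:
    """Synthetic DEM of one of four kinds.

    flat: constant ``value``; plane: constant ``gradient`` (dz/dx) along
    ``axis``; gaussian_hill: peak of ``height`` m and width ``sigma_m``;
    fractal: spectral 1/f**spectral_exponent noise scaled to ``relief`` m.
    """
    nrows, ncols = shape
    rng = np.random.default_rng(seed)
    if kind == "flat":
        z = np.full(shape, float(params.get("value", 0.0)))
    elif kind == "plane":
        gradient = float(params.get("gradient", 0.1))
        axis = int(params.get("axis", 1))
        coord = np.arange(shape[axis]) * cell_size * gradient
        z = np.broadcast_to(coord if axis == 1 else coord[:, None],
                            shape).astype(float).copy()
    elif kind == "gaussian_hill":
        height = float(params.get("height", 500.0))
        sigma = float(params.get("sigma_m", shape[0] * cell_size / 6))
        r = np.arange(nrows) * cell_size
        c = np.arange(ncols) * cell_size
        rr, cc = np.meshgrid(r - r.mean(), c - c.mean(), indexing="ij")
        z = height * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma ** 2))
    elif kind == "fractal":
        expo = float(params.get("spectral_exponent", 2.0))
        relief = float(params.get("relief", 300.0))
        fr = np.fft.fftfreq(nrows)[:, None]
        fc = np.fft.fftfreq(ncols)[None, :]
        radius = np.hypot(fr, fc)
        radius[0, 0] = np.inf
        amp = radius ** (-expo / 2)
        phase = rng.uniform(0, 2 * np.pi, size=shape)
        spectrum = amp * np.exp(1j * phase)
        z = np.real(np.fft.ifft2(spectrum))
        z = (z - z.min()) / (z.max() - z.min()) * relief
    else:
        raise ScenarioError(f"unknown DEM kind {kind!r}")
    return DEMRaster(elevation=z, cell_size=cell_size)


@dataclass
class NPPRegime:
    """One climatic regime: mean NPP level held for a duration."""

    duration_years: float
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_years <= 0:
            raise ScenarioError("regime duration must be > 0")


def generate_npp_series(regimes: Sequence[NPPRegime], step_years: float,
                        seed: int = 0, start_bp: float = 45_000.0,
                        ar_coefficient: float = 0.6) -> NPPSeries:
    """NPP series with regime shifts and AR(1) noise, clipped at zero.

    Emulates stadial/interstadial alternation: each regime contributes
    duration/step samples around its mean with autocorrelated noise.
    """
    rng = np.random.default_rng(seed)
    years = []
    values = []
    t = start_bp
    e = 0.0
    phi = ar_coefficient
    for regime in regimes:
        n = int(round(regime.duration_years / step_years))
        innov_sd = regime.sd * np.sqrt(1 - phi ** 2) if regime.sd > 0 else 0.0
        for _ in range(n):
            e = phi * e + rng.normal(0.0, innov_sd) if innov_sd else phi * e
            years.append(t)
            values.append(max(0.0, regime.mean + e))
            t -= step_years
    return NPPSeries(np.array(years), np.array(values))
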