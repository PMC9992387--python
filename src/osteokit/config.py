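"""Run configuration: one TOML file drives every analysis stage.

Holds the printed constants of the study design (30% slope threshold,
72 / 129 minute isochrones, diversity basis) together with MCMC settings
and the mandatory seed for every stochastic stage.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("osteokit")


@dataclass
class MCMCSettings:
    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 1
    proposal_sd_alpha: float = 0.08
    proposal_sd_beta: float = 0.45
    beta_max: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be > 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class HikingParameters:
    """Anisotropic walking-speed model (Tobler's hiking function).

    Speed in km/h as a function of the slope dh/dx along the direction of
    movement: v = base_speed * exp(-decay * |dh/dx + offset|).  The offset
    makes the maximum speed occur on a gentle downhill, so uphill and
    downhill times between the same two cells differ.
    """

    base_speed_kmh: float = 6.0
    decay: float = 3.5
    offset: float = 0.05

    def speed(self, gradient: float) -> float:
        import math
        return self.base_speed_kmh * math.exp(
            -self.decay * abs(gradient + self.offset))


@dataclass
class AnalysisConfig:
    taxa: list[str] = field(default_factory=list)
    rounding_decimals: int = 2
    diversity_basis: str = "MNI"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    hiking: HikingParameters = field(default_factory=HikingParameters)
    isochrone_minutes: tuple[float, ...] = (72.0, 129.0)
    slope_threshold_pct: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diversity_basis not in ("NISP", "MNI"):
            raise ValueError("diversity_basis must be NISP or MNI")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is required for stochastic stages")
        return self.seed


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    mcmc = MCMCSettings(**raw.get("mcmc", {}))
    hiking = HikingParameters(**raw.get("hiking", {}))
    cfg = AnalysisConfig(
        taxa=list(raw.get("taxa", [])),
        rounding_decimals=raw.get("rounding_decimals", 2),
        diversity_basis=raw.get("diversity_basis", "MNI"),
        mcmc=mcmc,
        hiking=hiking,
        isochrone_minutes=tuple(raw.get("isochrone_minutes", (72.0, 129.0))),
        slope_threshold_pct=raw.get("slope_threshold_pct", 30.0),
        seed=raw.get("seed"),
    )
    if cfg.seed is not None and cfg.mcmc.seed is None:
        cfg.mcmc.seed = cfg.seed
    log.info("loaded config from %s: %s", path, cfg)
    return cfg
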