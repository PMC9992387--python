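"""Bayesian inference of carcass transport and density-mediated attrition.

The skeletal-part profile of a taxon at a site is modelled as the outcome
of two processes acting on complete skeletons:

* *transport preference* alpha in [-1, 1]: the relative chance that an
  axial versus appendicular element reaches the site.  Element weights are
  linear in alpha, ``1 - alpha`` for axial and ``1 + alpha`` for
  appendicular, so alpha = 0 means complete transport, alpha = 1 a purely
  appendicular assemblage and alpha = -1 a purely axial one.

* *attrition* beta >= 0: density-mediated post-depositional destruction.
  An element of maximum bone density d in (0, 1] survives with probability
  d**beta, so beta = 0 preserves everything and large beta concentrates
  the surviving assemblage on the densest elements.

Observed MNE counts are multinomial over element identities with
probabilities proportional to skeleton_count x transport weight x
survivorship.  Priors are uniform on the parameter boxes; the posterior is
sampled with Gaussian random-walk Metropolis, reflecting proposals at the
box boundaries, and summarised with a split-half R-hat diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import MCMCSettings
from .records import SkeletonTemplate

log = logging.getLogger("osteokit")


class SkeletalBayesError(ValueError):
    pass


def transport_weight(region: str, alpha: float) -> float:
    """Relative transport weight of an element region at preference alpha."""
    if not -1.0 <= alpha <= 1.0:
        raise SkeletalBayesError(f"alpha must be in [-1, 1], got {alpha}")
    if region == "axial":
        return 1.0 - alpha
    if region == "appendicular":
        return 1.0 + alpha
    raise SkeletalBayesError(f"unknown region {region!r}")


def survivorship(d: float, beta: float) -> float:
    """Survival probability d**beta of an element of maximum density d."""
    if d <= 0:
        raise SkeletalBayesError(f"density must be > 0, got {d}")
    if beta < 0:
        raise SkeletalBayesError(f"beta must be >= 0, got {beta}")
    return d ** beta


def _template_arrays(template: SkeletonTemplate,
                     elements: list[str] | None = None
                     ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    names = list(elements) if elements is not None else list(
        template.element_names())
    for e in names:
        if e not in template:
            raise SkeletalBayesError(
                f"element {e!r} missing from template {template.taxon!r}")
    counts = np.array([template[e].skeleton_count for e in names], float)
    dens = np.array([template[e].density for e in names], float)
    axial = np.array([template[e].region == "axial" for e in names])
    return names, counts, dens, axial


def expected_profile(template: SkeletonTemplate, alpha: float, beta: float,
                     elements: list[str] | None = None) -> np.ndarray:
    """Expected element proportions p_i under (alpha, beta), summing to 1."""
    _, counts, dens, axial = _template_arrays(template, elements)
    w = np.where(axial, 1.0 - alpha, 1.0 + alpha)
    if not -1.0 <= alpha <= 1.0:
        raise SkeletalBayesError(f"alpha must be in [-1, 1], got {alpha}")
    p = counts * w * dens ** beta
    total = p.sum()
    if total <= 0:
        raise SkeletalBayesError(
            "degenerate model: all element probabilities are zero")
    return p / total


def log_likelihood(observed: dict[str, int] | np.ndarray,
                   template: SkeletonTemplate, alpha: float,
                   beta: float) -> float:
    """Multinomial log-likelihood of observed MNE counts (constant dropped)."""
    if isinstance(observed, dict):
        elements = list(observed)
        n = np.array([observed[e] for e in elements], float)
    else:
        elements = None
        n = np.asarray(observed, float)
    if (n < 0).any() or n.sum() <= 0:
        raise SkeletalBayesError("observed counts must be nonnegative with a "
                                 "positive total")
    p = expected_profile(template, alpha, beta, elements)
    if np.any((p == 0) & (n > 0)):
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(np.where(n > 0, n * np.log(p), 0.0).sum())


def preservation_fraction(template: SkeletonTemplate, beta: float,
                          elements: list[str] | None = None) -> float:
    """Expected fraction of the original skeleton surviving attrition beta."""
    if beta < 0:
        raise SkeletalBayesError("beta must be >= 0")
    _, counts, dens, _ = _template_arrays(template, elements)
    return float((counts * dens ** beta).sum() / counts.sum())


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflect into [lo, hi]; enough for proposal scales << interval width
    span = hi - lo
    while not lo <= x <= hi:
        if x < lo:
            x = 2 * lo - x
        elif x > hi:
            x = 2 * hi - x
        if span <= 0:
            return lo
    return x


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction from one chain split into two halves."""
    n = len(draws) // 2
    halves = np.stack([draws[:n], draws[n:2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(math.sqrt(var_plus / within))


@dataclass
class SkeletalBayesResult:
    alpha_draws: np.ndarray
    beta_draws: np.ndarray
    acceptance_rate: float
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)
    preservation_draws: np.ndarray | None = None

    def credible_interval(self, param: str,
                          level: float = 0.95) -> tuple[float, float]:
        draws = self.alpha_draws if param == "alpha" else self.beta_draws
        lo = (1 - level) / 2
        return (float(np.quantile(draws, lo)),
                float(np.quantile(draws, 1 - lo)))


def fit_posterior(observed: dict[str, int], template: SkeletonTemplate,
                  settings: MCMCSettings) -> SkeletalBayesResult:
    """Sample the (alpha, beta) posterior by random-walk Metropolis.

    Deterministic given (seed, settings, data).  Emits a warning below an
    observed total of 20 (the sampler still runs) and when the split-half
    R-hat of either parameter exceeds 1.1.
    """
    if settings.seed is None:
        raise SkeletalBayesError("MCMC requires a seed")
    elements = list(observed)
    n = np.array([observed[e] for e in elements], float)
    total = int(n.sum())
    if total < 20:
        log.warning("observed MNE total %d < 20: posterior will be diffuse",
                    total)
    if total < 50:
        log.warning("observed MNE total %d < 50: below the customary "
                    "applicability threshold for skeletal-profile inference",
                    total)

    _, counts, dens, axial = _template_arrays(template, elements)
    log_dens = np.log(dens)

    def logpost(alpha: float, beta: float) -> float:
        w = np.where(axial, 1.0 - alpha, 1.0 + alpha)
        logp_un = np.log(counts * w, where=counts * w > 0,
                         out=np.full_like(counts, -np.inf)) + beta * log_dens
        norm = np.logaddexp.reduce(logp_un)
        if not np.isfinite(norm):
            return -np.inf
        logp = logp_un - norm
        if np.any(np.isneginf(logp) & (n > 0)):
            return -np.inf
        return float(np.where(n > 0, n * logp, 0.0).sum())

    rng = np.random.default_rng(settings.seed)
    alpha, beta = 0.0, 1.0
    lp = logpost(alpha, beta)
    a_draws, b_draws = [], []
    accepted = 0
    for it in range(settings.iterations):
        prop_a = _reflect(alpha + rng.normal(0, settings.proposal_sd_alpha),
                          -1.0, 1.0)
        prop_b = _reflect(beta + rng.normal(0, settings.proposal_sd_beta),
                          0.0, settings.beta_max)
        lp_new = logpost(prop_a, prop_b)
        if math.log(rng.random()) < lp_new - lp:
            alpha, beta, lp = prop_a, prop_b, lp_new
            accepted += 1
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            a_draws.append(alpha)
            b_draws.append(beta)

    a = np.array(a_draws)
    b = np.array(b_draws)
    result = SkeletalBayesResult(
        alpha_draws=a, beta_draws=b,
        acceptance_rate=accepted / settings.iterations,
        preservation_draws=np.array(
            [preservation_fraction(template, bb, elements) for bb in b]),
    )
    for name, draws in (("alpha", a), ("beta", b)):
        lo, hi = np.quantile(draws, [0.025, 0.975])
        result.summary[name] = {
            "mean": float(draws.mean()),
            "median": float(np.median(draws)),
            "ci95_low": float(lo),
            "ci95_high": float(hi),
        }
        result.rhat[name] = split_rhat(draws)
        if result.rhat[name] > 1.1:
            log.warning("split R-hat for %s is %.3f (> 1.1): chain may not "
                        "have converged", name, result.rhat[name])
    log.info("MCMC finished: acceptance %.1f%%, alpha mean %.3f, beta mean "
             "%.3f", 100 * result.acceptance_rate,
             result.summary["alpha"]["mean"], result.summary["beta"]["mean"])
    return result


def grid_posterior(observed: dict[str, int], template: SkeletonTemplate,
                   n_alpha: int = 101, n_beta: int = 101,
                   beta_max: float = 12.0
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised posterior on a regular (alpha, beta) grid.

    Direct evaluation under the uniform priors; serves as the deterministic
    cross-check of the Metropolis sampler.
    """
    alphas = np.linspace(-1.0, 1.0, n_alpha)
    betas = np.linspace(0.0, beta_max, n_beta)
    elements = list(observed)
    n = np.array([observed[e] for e in elements], float)
    _, counts, dens, axial = _template_arrays(template, elements)
    w = np.where(axial[None, :], 1.0 - alphas[:, None], 1.0 + alphas[:, None])
    base = counts[None, :] * w                      # (n_alpha, k)
    surv = dens[None, :] ** betas[:, None]          # (n_beta, k)
    p = base[:, None, :] * surv[None, :, :]         # (n_alpha, n_beta, k)
    tot = p.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p / tot)
    ll = np.where(n[None, None, :] > 0, n[None, None, :] * logp, 0.0)
    ll = np.where(np.isnan(ll), -np.inf, ll).sum(axis=2)
    ll -= ll.max()
    post = np.exp(ll)
    post /= post.sum()
    return alphas, betas, post
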