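"""Transport/attrition model: likelihood geometry and posterior sampling."""

import numpy as np
import pytest

from osteokit.bayes import (
    SkeletalBayesError,
    expected_profile,
    fit_posterior,
    grid_posterior,
    log_likelihood,
    preservation_fraction,
    survivorship,
    transport_weight,
)
from osteokit.config import MCMCSettings
from osteokit.records import SkeletonTemplate, TemplateElement
from osteokit.synth import caprine_template


def test_transport_weight_endpoints():
    assert transport_weight("axial", 0.0) == transport_weight(
        "appendicular", 0.0) == 1.0
    assert transport_weight("axial", 1.0) == 0.0
    assert transport_weight("appendicular", -1.0) == 0.0
    with pytest.raises(SkeletalBayesError):
        transport_weight("axial", 1.5)


def test_survivorship_closed_forms():
    assert survivorship(0.3, 0.0) == 1.0
    assert survivorship(1.0, 7.0) == 1.0
    assert survivorship(0.5, 2.0) == 0.25
    with pytest.raises(SkeletalBayesError):
        survivorship(0.0, 1.0)


def test_survivorship_decreasing_in_beta():
    vals = [survivorship(0.7, b) for b in (0.0, 1.0, 3.0, 8.0)]
    assert vals == sorted(vals, reverse=True)


@pytest.fixture
def tri_template():
    return SkeletonTemplate(taxon="t", elements=(
        TemplateElement("a", 1, "axial", 0.4),
        TemplateElement("b", 2, "appendicular", 0.8),
        TemplateElement("c", 1, "appendicular", 0.6),
    ))


def test_expected_profile_neutral_is_skeleton_counts(tri_template):
    p = expected_profile(tri_template, 0.0, 0.0)
    assert p == pytest.approx([0.25, 0.5, 0.25])


def test_expected_profile_hand_normalised(tri_template):
    # alpha=0.5, beta=1: weights (1*0.5*0.4, 2*1.5*0.8, 1*1.5*0.6)
    raw = np.array([0.2, 2.4, 0.9])
    p = expected_profile(tri_template, 0.5, 1.0)
    assert p == pytest.approx(raw / raw.sum())


def test_expected_profile_concentrates_on_densest_at_large_beta(tri_template):
    p = expected_profile(tri_template, 0.0, 60.0)
    assert p[1] > 0.999  # element b has the highest density


def test_likelihood_maximised_at_generating_parameters(tri_template):
    alpha_star, beta_star = 0.3, 1.2
    p = expected_profile(tri_template, alpha_star, beta_star)
    observed = dict(zip(tri_template.element_names(), (1000 * p).round()))
    grid = [(a, b) for a in np.linspace(-0.9, 0.9, 31)
            for b in np.linspace(0.0, 6.0, 31)]
    best = max(grid, key=lambda ab: log_likelihood(observed, tri_template,
                                                   *ab))
    assert abs(best[0] - alpha_star) < 0.1
    assert abs(best[1] - beta_star) < 0.25


def test_likelihood_invariant_to_element_order(tri_template):
    obs = {"a": 3, "b": 7, "c": 2}
    ll = log_likelihood(obs, tri_template, 0.2, 1.0)
    obs_rev = dict(reversed(list(obs.items())))
    assert log_likelihood(obs_rev, tri_template, 0.2, 1.0) == pytest.approx(ll)


def test_preservation_fraction_closed_forms(tri_template):
    assert preservation_fraction(tri_template, 0.0) == 1.0
    two = SkeletonTemplate(taxon="t", elements=(
        TemplateElement("a", 1, "axial", 0.5),
        TemplateElement("b", 1, "appendicular", 0.5)))
    assert preservation_fraction(two, 1.0) == pytest.approx(0.5)


def test_preservation_fraction_decreasing_in_beta(tri_template):
    vals = [preservation_fraction(tri_template, b) for b in (0, 1, 2, 6)]
    assert vals == sorted(vals, reverse=True)
    # at strong attrition only a small share of the skeleton remains
    assert preservation_fraction(tri_template, 5.78) < 0.3


def test_posterior_deterministic_given_seed(tri_template):
    obs = {"a": 10, "b": 30, "c": 12}
    settings = MCMCSettings(iterations=2000, burn_in=200, seed=13)
    r1 = fit_posterior(obs, tri_template, settings)
    r2 = fit_posterior(obs, tri_template, settings)
    assert np.array_equal(r1.alpha_draws, r2.alpha_draws)
    assert np.array_equal(r1.beta_draws, r2.beta_draws)


def test_null_recovery_covers_zero():
    tpl = caprine_template(20)
    p = expected_profile(tpl, 0.0, 0.0)
    rng = np.random.default_rng(3)
    obs = dict(zip(tpl.element_names(),
                   rng.multinomial(5000, p).tolist()))
    res = fit_posterior(obs, tpl, MCMCSettings(iterations=8000, burn_in=1000,
                                               seed=4))
    lo, hi = res.credible_interval("alpha")
    assert lo <= 0.0 <= hi
    lo, hi = res.credible_interval("beta")
    assert lo <= 0.05  # beta prior boundary: CI must reach (near) zero


def test_label_swap_negates_alpha_posterior():
    tpl = caprine_template(10)
    swapped = SkeletonTemplate(taxon=tpl.taxon, elements=tuple(
        TemplateElement(e.element, e.skeleton_count,
                        "axial" if e.region == "appendicular"
                        else "appendicular", e.density)
        for e in tpl.elements), habitat=tpl.habitat, rank=tpl.rank)
    p = expected_profile(tpl, 0.4, 1.0)
    rng = np.random.default_rng(8)
    obs = dict(zip(tpl.element_names(), rng.multinomial(400, p).tolist()))
    settings = MCMCSettings(iterations=12000, burn_in=2000, seed=21)
    mean = fit_posterior(obs, tpl, settings).summary["alpha"]["mean"]
    mean_swapped = fit_posterior(obs, swapped,
                                 settings).summary["alpha"]["mean"]
    assert mean_swapped == pytest.approx(-mean, abs=0.05)


def test_acceptance_rate_in_healthy_range(tri_template):
    obs = {"a": 40, "b": 90, "c": 50}
    res = fit_posterior(obs, tri_template,
                        MCMCSettings(iterations=5000, burn_in=500, seed=2))
    assert 0.15 < res.acceptance_rate < 0.65
    assert all(-1 <= a <= 1 for a in res.alpha_draws)
    assert all(0 <= b <= 12 for b in res.beta_draws)


def test_grid_posterior_normalised(tri_template):
    _, _, post = grid_posterior({"a": 5, "b": 20, "c": 8}, tri_template,
                                n_alpha=41, n_beta=41)
    assert post.sum() == pytest.approx(1.0)
    assert (post >= 0).all()


def test_rhat_cross_checked_against_arviz(tri_template):
    arviz = pytest.importorskip("arviz")
    from osteokit.bayes import split_rhat
    rng = np.random.default_rng(0)
    draws = rng.normal(size=4000)
    ours = split_rhat(draws)
    n = len(draws) // 2
    theirs = float(arviz.rhat(draws[:2 * n].reshape(2, n)))
    assert ours == pytest.approx(theirs, abs=0.02)
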