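"""NPP series statistics, Mann-Whitney and Spearman with exact oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from osteokit.nppstats import (
    NPPSeries,
    NPPStatsError,
    mann_whitney,
    npp_diversity_correlation,
    spearman,
    unit_npp_stats,
)
from osteokit.synth import NPPRegime, generate_npp_series


def test_unit_stats_constant_series():
    s = NPPSeries(np.arange(40_000, 39_000, -100.0), np.full(10, 0.2))
    out = unit_npp_stats(s, (39_800, 39_300))
    assert out["mean"] == pytest.approx(0.2)
    assert out["sd"] == pytest.approx(0.0, abs=1e-12)
    assert out["n"] == 6


def test_unit_stats_hand_arithmetic():
    s = NPPSeries(np.array([42_000.0, 41_000.0, 40_000.0]),
                  np.array([0.1, 0.2, 0.3]))
    out = unit_npp_stats(s, (42_000, 40_000))
    assert out["mean"] == pytest.approx(0.2)
    assert out["sd"] == pytest.approx(0.1)


def test_unit_stats_invariant_to_series_order():
    rng = np.random.default_rng(0)
    years = np.arange(45_000, 40_000, -50.0)
    vals = rng.uniform(0.1, 0.4, years.size)
    perm = rng.permutation(years.size)
    a = unit_npp_stats(NPPSeries(years, vals), (44_000, 42_000))
    b = unit_npp_stats(NPPSeries(years[perm], vals[perm]), (44_000, 42_000))
    assert a == pytest.approx(b)


def test_unit_stats_empty_overlap_errors():
    s = NPPSeries(np.array([40_000.0, 39_000.0]), np.array([0.2, 0.2]))
    with pytest.raises(NPPStatsError):
        unit_npp_stats(s, (30_000, 29_000))


def test_mann_whitney_identical_samples_p_one():
    u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_mann_whitney_fully_separated_exact():
    u, p = mann_whitney([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)


@pytest.mark.parametrize("seed", range(12))
def test_mann_whitney_matches_exhaustive_permutation(seed):
    rng = np.random.default_rng(seed)
    na, nb = rng.integers(2, 4), rng.integers(2, 4)
    pooled = rng.integers(0, 5, na + nb).astype(float)  # ties likely
    a, b = pooled[:na], pooled[na:]
    u, p = mann_whitney(a, b)

    def u_stat(x, y):
        d = np.subtract.outer(x, y)
        return (d > 0).sum() + 0.5 * (d == 0).sum()

    null = [u_stat(pooled[list(idx)],
                   pooled[[i for i in range(na + nb) if i not in idx]])
            for idx in itertools.combinations(range(na + nb), na)]
    null = np.array(null)
    p_oracle = min(1.0, 2 * min((null <= u + 1e-9).mean(),
                                (null >= u - 1e-9).mean()))
    assert p == pytest.approx(p_oracle)


def test_mann_whitney_large_sample_matches_scipy():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 30), rng.normal(0.7, 1, 25)
    _, p = mann_whitney(a, b)
    _, p_ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic")
    assert p == pytest.approx(float(p_ref))


def test_spearman_perfect_monotone():
    rho, _ = spearman([1, 2, 3, 4], [10, 20, 25, 70])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman([1, 2, 3, 4], [5, 4, 3, 2])
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_input_rejected():
    with pytest.raises(NPPStatsError):
        spearman([1, 1, 1], [1, 2, 3])


@pytest.mark.parametrize("seed", range(8))
def test_spearman_exact_p_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = 5
    x = rng.uniform(size=n)
    y = rng.integers(0, 3, n).astype(float)  # ties in y
    if np.all(y == y[0]):
        y[0] += 1.0
    rho, p = spearman(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / math.sqrt((a ** 2).sum()
                                               * (b ** 2).sum()))

    null = [abs(rho_of(rx, np.array(perm)))
            for perm in itertools.permutations(ry)]
    p_oracle = np.mean([v >= abs(rho) - 1e-12 for v in null])
    assert p == pytest.approx(p_oracle)


def test_spearman_large_sample_matches_scipy():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    rho, p = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert rho == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


def test_npp_diversity_correlation_monotone_and_shuffled():
    npp = {f"u{i}": 0.1 + 0.02 * i for i in range(6)}
    diversity = {"primary": {f"u{i}": 2.0 + 0.3 * i for i in range(6)}}
    out = npp_diversity_correlation(npp, diversity)
    assert out["primary"]["rho"] == pytest.approx(1.0)
    # shuffled pairings decorrelate on average
    rng = np.random.default_rng(0)
    rhos = []
    vals = list(diversity["primary"].values())
    for _ in range(50):
        perm = rng.permutation(vals)
        shuffled = {"all": dict(zip(npp, perm))}
        rhos.append(npp_diversity_correlation(npp, shuffled)["all"]["rho"])
    assert abs(np.mean(rhos)) < 0.25


def test_npp_diversity_correlation_needs_three_units():
    with pytest.raises(NPPStatsError):
        npp_diversity_correlation({"a": 0.1, "b": 0.2},
                                  {"g": {"a": 2.0, "b": 3.0}})


def test_generated_regimes_recover_means():
    regimes = [NPPRegime(10_000, 0.33, 0.02), NPPRegime(8_000, 0.19, 0.02)]
    s = generate_npp_series(regimes, step_years=50.0, seed=6,
                            start_bp=45_000.0)
    first = s.npp[:200]
    second = s.npp[200:]
    se = 0.02 / np.sqrt(200 / 10)  # AR(1) reduces the effective n
    assert first.mean() == pytest.approx(0.33, abs=2.5 * se)
    assert second.mean() == pytest.approx(0.19, abs=2.5 * se)
    assert (s.npp >= 0).all()


def test_generated_series_deterministic():
    regimes = [NPPRegime(2_000, 0.25, 0.03)]
    a = generate_npp_series(regimes, 100.0, seed=9)
    b = generate_npp_series(regimes, 100.0, seed=9)
    assert np.array_equal(a.npp, b.npp) and np.array_equal(a.years_bp,
                                                           b.years_bp)
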