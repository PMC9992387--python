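"""Net-primary-productivity series statistics and diversity correlation.

NPP series (kg/m^2/year) are consumed as externally produced data; this
module only slices them to archaeological occupation intervals, compares
units with the Mann-Whitney-Wilcoxon test and correlates unit NPP with
diet-breadth values via Spearman's rank correlation.

Both tests are two-sided.  Small samples get exact p-values: the
Mann-Whitney null distribution is enumerated over all ways to assign the
pooled values to the two groups (which handles ties, unlike the standard
exact tables), and the Spearman permutation null enumerates all n!
orderings for n <= 7.  Larger samples use the tie-corrected normal and
Student-t approximations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MW_EXACT_LIMIT = 12    # exact enumeration when n_a + n_b <= this
SPEARMAN_EXACT_LIMIT = 7


class NPPStatsError(ValueError):
    pass


@dataclass
class NPPSeries:
    """Dated NPP values with per-unit occupation intervals (years BP)."""

    years_bp: np.ndarray
    npp: np.ndarray
    units: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years_bp = np.asarray(self.years_bp, float)
        self.npp = np.asarray(self.npp, float)
        if self.years_bp.shape != self.npp.shape:
            raise NPPStatsError("years and NPP must be the same length")
        if (self.npp < 0).any():
            raise NPPStatsError("NPP must be nonnegative")
        for unit, (start, end) in self.units.items():
            if start < end:
                raise NPPStatsError(
                    f"unit {unit}: start must be older (larger BP) than end")

    def slice(self, interval: tuple[float, float]) -> np.ndarray:
        start, end = interval
        sel = (self.years_bp <= start) & (self.years_bp >= end)
        return self.npp[sel]


def read_npp_series(series_path: str | Path,
                    units_path: str | Path | None = None) -> NPPSeries:
    df = pd.read_csv(series_path)
    units: dict[str, tuple[float, float]] = {}
    if units_path is not None:
        u = pd.read_csv(units_path)
        units = {row.unit: (float(row.start_bp), float(row.end_bp))
                 for row in u.itertuples()}
    return NPPSeries(df["year_bp"].to_numpy(), df["npp_kg_m2_yr"].to_numpy(),
                     units)


def unit_npp_stats(series: NPPSeries,
                   interval: tuple[float, float]) -> dict[str, float]:
    """Mean, sample SD and n of NPP values inside an occupation interval."""
    vals = series.slice(interval)
    if vals.size == 0:
        raise NPPStatsError(f"no NPP values inside interval {interval}")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {"mean": float(vals.mean()), "sd": sd, "n": int(vals.size)}


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # U for sample a: pairs a > b, ties counting one half
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a: Sequence[float],
                 b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and two-sided p.

    Exact enumeration of the permutation null when the pooled size is at
    most 12; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise NPPStatsError("both samples must be nonempty")
    u = _u_statistic(a, b)
    n = a.size + b.size
    if n <= MW_EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        us = []
        for idx in itertools.combinations(range(n), a.size):
            sel = np.zeros(n, bool)
            sel[list(idx)] = True
            us.append(_u_statistic(pooled[sel], pooled[~sel]))
        us = np.asarray(us)
        eps = 1e-9
        p_low = float((us <= u + eps).mean())
        p_high = float((us >= u - eps).mean())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        p = float(p)
    return u, p


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    return float((rx * ry).sum()) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho on midranks and a two-sided p-value.

    p is exact (full permutation null over orderings of y) for n <= 7,
    otherwise the usual Student-t approximation with n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise NPPStatsError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise NPPStatsError("constant input: rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= SPEARMAN_EXACT_LIMIT:
        eps = 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.asarray(perm))) >= abs(rho) - eps:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def npp_diversity_correlation(
        npp_means: Mapping[str, float],
        diversity: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Spearman correlation of unit NPP with diversity per consumer group.

    ``diversity`` maps consumer group (e.g. "primary", "secondary", "all")
    to per-unit inverse Simpson values; only units present in both inputs
    enter each correlation, and at least three are required.
    """
    out = {}
    for group, values in diversity.items():
        units = [u for u in values if u in npp_means]
        if len(units) < 3:
            raise NPPStatsError(
                f"consumer group {group!r}: need >= 3 units with both NPP "
                f"and diversity, got {len(units)}")
        rho, p = spearman([npp_means[u] for u in units],
                          [values[u] for u in units])
        out[group] = {"rho": rho, "p": p, "n": len(units)}
    return out
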