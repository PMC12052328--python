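"""Shared fixtures and independent oracles.

The oracle functions here are deliberately written from first principles
(plain loops, explicit enumeration, closed forms) and never call into the
package's own computation paths, so implementation/oracle agreement is a
real cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from novascore.instrument import default_instrument


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


def oracle_category_points(
    r1: int, r3: int, r4: int, tie_policy: str = "pair_incorrect",
    one_pair_policy: str = "zero",
) -> int:
    """Brute-force pairwise scorer, independent of novascore.scoring."""
    pairs = [(r1, r3), (r1, r4), (r3, r4)]
    n_correct = sum(1 for hi, lo in pairs if hi > lo)
    if tie_policy == "zero_category" and len({r1, r3, r4}) < 3:
        return 0
    if n_correct == 3:
        return 2
    if n_correct == 2:
        return 1
    if n_correct == 1 and one_pair_policy == "one_point":
        return 1
    return 0


def oracle_mannwhitney_exact_p(a, b) -> tuple[float, float]:
    """(U of a, two-sided exact p) by enumerating every group assignment."""
    pooled = list(a) + list(b)
    n1 = len(a)
    # midranks
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1

    def u_of(indices):
        rsum = sum(ranks[i] for i in indices)
        return rsum - n1 * (n1 + 1) / 2

    observed = u_of(range(n1))
    mu = n1 * (len(pooled) - n1) / 2
    d_obs = abs(observed - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= d_obs - 1e-12:
            hits += 1
    return observed, hits / total


def oracle_ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Normal-equations solve (X'X)^{-1} X'y with an intercept column first."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


def oracle_variance_components(recalls: pd.DataFrame) -> dict:
    """Hand-rolled one-way random-effects moments (explicit sums of squares)."""
    groups = {}
    for row in recalls.itertuples(index=False):
        groups.setdefault(row.respondent_id, []).append(float(row.upf_percent))
    k = len(groups)
    N = sum(len(v) for v in groups.values())
    grand = sum(sum(v) for v in groups.values()) / N
    ssw = sum(
        (y - sum(v) / len(v)) ** 2 for v in groups.values() for y in v
    )
    ssb = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
    vw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - sum(len(v) ** 2 for v in groups.values()) / N) / (k - 1)
    return {
        "grand_mean": grand,
        "var_within": vw,
        "var_between": max(0.0, (msb - vw) / n0),
        "n0": n0,
    }


def rating_pmf_at_chance(noise_sd: float, lo: int = 1, hi: int = 10,
                         center: float = 6.0) -> dict[int, float]:
    """Distribution of clamp(round(center + N(0, sd))) over the scale."""
    from scipy.stats import norm

    pmf = {}
    for v in range(lo, hi + 1):
        upper = math.inf if v == hi else v + 0.5
        lower = -math.inf if v == lo else v - 0.5
        pmf[v] = norm.cdf(upper, center, noise_sd) - norm.cdf(lower, center, noise_sd)
    return pmf
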