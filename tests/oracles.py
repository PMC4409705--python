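"""Independent brute-force oracles used by the test suite.

These are deliberately naive reimplementations (explicit loops, textbook
formulas) kept separate from the package so they can serve as references.
"""

from __future__ import annotations

import math

import numpy as np


def average_ranks(values) -> list[float]:
    """Average ranks (1-based) computed by explicit sorting, ties averaged."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # mean of 1-based positions i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks.

    Valid with ties (the rank-difference shortcut formula is not); reduces
    to 1 - 6*sum(d^2)/(n*(n^2-1)) when all values are distinct.
    """
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def spearman_of_bivariate_normal(rho: float) -> float:
    """Population Spearman correlation of a bivariate normal with Pearson rho."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


def lognormal_pair_targets(sigma_log: float) -> tuple[float, float]:
    """(median fold change, sd of log fold change) for iid lognormal partners.

    The log-ratio is N(0, 2*sigma_log^2); the fold change is exp(|log-ratio|),
    whose median is exp(sqrt(2)*sigma_log*z_{0.75}).
    """
    from scipy.stats import norm

    z75 = norm.ppf(0.75)
    return math.exp(math.sqrt(2.0) * sigma_log * z75), math.sqrt(2.0) * sigma_log


def median_fold_change_mc_se(sigma_log: float, n: int) -> float:
    """Asymptotic Monte-Carlo SE of the sample median fold change.

    Delta method through exp() around the median of |N(0, sqrt(2)*sigma)|.
    """
    from scipy.stats import norm

    s = math.sqrt(2.0) * sigma_log
    m = s * norm.ppf(0.75)
    density = 2.0 * norm.pdf(m, scale=s)  # density of the folded normal at m
    se_m = 1.0 / (2.0 * density * math.sqrt(n))
    return math.exp(m) * se_m


def sd_mc_se(sigma: float, n: int) -> float:
    """Approximate SE of a sample sd of n normal observations."""
    return sigma / math.sqrt(2.0 * n)


def random_ties_sample(rng: np.random.Generator, n: int, low: int = 0, high: int = 5):
    """Small integer sample guaranteed to contain ties with high probability."""
    return rng.integers(low, high, size=n).astype(float)
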