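"""Statistics for symmetric protein-pair data.

The observational unit throughout is an unordered pair of interacting
proteins, each carrying a value of one translational parameter. Because
the order within a pair is arbitrary, estimators must be (exactly or in
distribution) invariant to swapping partners:

* **Spearman correlation** between first and second partners, with a 95%
  confidence interval. The default interval is the Fisher z-transform with
  the Bonett-Wright standard error ``sqrt((1 + rho^2/2)/(n-3))``, the
  Spearman-specific asymptotic variance (the plain Pearson-style
  ``1/sqrt(n-3)`` measurably undercovers for rank correlations); plain
  Fisher and a pair-resampling bootstrap are selectable.
* **Difference between two independent correlations** with the asymmetric
  interval of Zou (2007), built from each correlation's own CI endpoints:
  for estimates r1 (CI ``l1..u1``) and r2 (CI ``l2..u2``),

  .. math::

     L = r_1 - r_2 - \\sqrt{(r_1-l_1)^2 + (u_2-r_2)^2}, \\qquad
     U = r_1 - r_2 + \\sqrt{(u_1-r_1)^2 + (r_2-l_2)^2}.

* **Fold change** within a pair: larger value over smaller, always >= 1,
  so that medians of the ratio distribution are comparable across sets.
  Its logarithm (without the numerator restriction) is symmetric around 0,
  and its standard deviation is a second, scale-free tightness measure.
* **Bootstrap intervals** for medians and standard deviations, and for
  differences of those between independent sets, by normal approximation
  or the percentile method (2000 resamples by default).

Interval estimates are reported everywhere; no p-values are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .interactions import InteractionSet, Pair
from .params import ParamsTable

__all__ = [
    "PairedValues",
    "CorrelationEstimate",
    "DifferenceEstimate",
    "BootstrapInterval",
    "pair_values",
    "spearman_with_ci",
    "correlation_difference_ci",
    "fold_changes",
    "log_fold_changes",
    "bootstrap_statistic_ci",
    "bootstrap_difference_ci",
]


@dataclass(frozen=True)
class PairedValues:
    """Per-pair value couples for one parameter, ready for analysis."""

    parameter: str
    first: np.ndarray
    second: np.ndarray
    pair_ids: tuple[Pair, ...]

    def __post_init__(self):
        first = np.asarray(self.first, dtype=float)
        second = np.asarray(self.second, dtype=float)
        object.__setattr__(self, "first", first)
        object.__setattr__(self, "second", second)
        if not (len(first) == len(second) == len(self.pair_ids)):
            raise ValueError("first, second and pair_ids must have equal length")
        if len(first) < 1:
            raise ValueError("PairedValues needs at least one pair")
        if np.isnan(first).any() or np.isnan(second).any():
            raise ValueError("PairedValues must not contain absent values")

    @property
    def n(self) -> int:
        return len(self.first)

    def flipped(self) -> "PairedValues":
        """Swap every couple's orientation (a symmetry, not new data)."""
        return PairedValues(self.parameter, self.second.copy(), self.first.copy(), self.pair_ids)


def pair_values(
    edges: InteractionSet,
    table: ParamsTable,
    parameter: str,
    order_policy: str = "randomized",
    seed: int | None = 0,
) -> PairedValues:
    """Extract one (first, second) value couple per pair.

    ``order_policy``:

    * ``"as-loaded"`` — couples follow the canonical stored pair order;
    * ``"randomized"`` — each couple's orientation is an independent fair
      coin flip, deterministic given ``seed``. This is the default since
      partner order carries no meaning, and it guarantees the symmetric
      dispersion of couples around the identity line that the correlation
      analysis assumes.

    ``edges`` must already be restricted to pairs analyzable for
    ``parameter``; an absent endpoint value is a hard error here.
    """
    pairs = sorted(edges.pairs)
    if not pairs:
        raise ValueError(f"no pairs to extract values from in set {edges.label!r}")
    firsts = table.values_for(parameter, [p[0] for p in pairs])
    seconds = table.values_for(parameter, [p[1] for p in pairs])
    bad = np.isnan(firsts) | np.isnan(seconds)
    if bad.any():
        pair = pairs[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"pair {pair} lacks a value of {parameter!r}; "
            "restrict_to_analyzable must be applied first"
        )
    if order_policy == "randomized":
        rng = np.random.default_rng(seed)
        flip = rng.random(len(pairs)) < 0.5
        firsts, seconds = np.where(flip, seconds, firsts), np.where(flip, firsts, seconds)
    elif order_policy != "as-loaded":
        raise ValueError(f"unknown order_policy {order_policy!r}")
    return PairedValues(parameter, firsts, seconds, tuple(pairs))


@dataclass(frozen=True)
class CorrelationEstimate:
    """A Spearman correlation with its confidence interval."""

    rho: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95
    method: str = "bonett-wright"

    def __post_init__(self):
        if not (self.ci_low <= self.rho <= self.ci_high):
            raise ValueError(
                f"inconsistent interval: [{self.ci_low}, {self.ci_high}] "
                f"does not bracket rho={self.rho}"
            )

    def width(self) -> float:
        return self.ci_high - self.ci_low


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    # average ranks for ties, Pearson correlation of the ranks
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def spearman_with_ci(
    pv: PairedValues,
    level: float = 0.95,
    method: str = "bonett-wright",
    reps: int = 2000,
    seed: int | None = 0,
) -> CorrelationEstimate:
    """Spearman rank correlation of the couples with a confidence interval.

    Methods
    -------
    ``bonett-wright`` (default)
        Fisher transform with standard error ``sqrt((1 + rho^2/2)/(n-3))``,
        the Spearman-specific asymptotic variance; gives near-nominal
        coverage both alone and inside the Zou difference interval.
    ``fisher``
        ``tanh(atanh(rho) ± z * 1/sqrt(n-3))``, the Pearson-style interval
        many standard tools apply to rank correlations.
    ``bootstrap``
        Percentile interval over ``reps`` resamples of pairs.

    Ties receive average ranks. Analytic methods require ``n >= 4``; a
    degenerate margin (zero variance) is a hard error.
    """
    x, y = pv.first, pv.second
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin: correlation undefined")
    rho = _spearman_rho(x, y)
    n = pv.n
    if method in ("fisher", "bonett-wright"):
        if n < 4:
            raise ValueError(f"analytic CI needs n >= 4, got n={n}")
        z = sps.norm.ppf(0.5 + level / 2)
        zr = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, rho)))
        if method == "fisher":
            se = 1.0 / math.sqrt(n - 3)
        else:
            se = math.sqrt((1 + rho**2 / 2) / (n - 3))
        lo, hi = math.tanh(zr - z * se), math.tanh(zr + z * se)
        # at |rho| = 1 the z-transform is unbounded and the interval
        # degenerates onto the boundary; keep it bracketing the estimate
        lo, hi = min(lo, rho), max(hi, rho)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(reps, n))
        boot = np.empty(reps)
        for k in range(reps):
            xi, yi = x[idx[k]], y[idx[k]]
            if np.ptp(xi) == 0 or np.ptp(yi) == 0:
                boot[k] = np.nan
            else:
                boot[k] = _spearman_rho(xi, yi)
        alpha = 1 - level
        lo, hi = np.nanquantile(boot, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(float(lo), rho), max(float(hi), rho)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return CorrelationEstimate(
        rho=rho, ci_low=float(lo), ci_high=float(hi), n=n, level=level, method=method
    )


@dataclass(frozen=True)
class DifferenceEstimate:
    """Difference of two independent correlations with a Zou-2007 interval."""

    delta: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    level: float = 0.95

    def __post_init__(self):
        if not (self.ci_low <= self.delta <= self.ci_high):
            raise ValueError("inconsistent difference interval")

    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def correlation_difference_ci(
    e1: CorrelationEstimate, e2: CorrelationEstimate, level: float = 0.95
) -> DifferenceEstimate:
    """Zou (2007) confidence interval for ``r1 - r2``, independent groups.

    The interval combines each correlation's own CI endpoints
    asymmetrically, so it respects the bounded, skewed sampling
    distribution of correlations near ±1 better than a naive
    difference-of-z interval.
    """
    for e in (e1, e2):
        if e.n is None or e.n < 4:
            raise ValueError("both estimates need sample sizes n >= 4")
    r1, r2 = e1.rho, e2.rho
    delta = r1 - r2
    lo = delta - math.sqrt((r1 - e1.ci_low) ** 2 + (e2.ci_high - r2) ** 2)
    hi = delta + math.sqrt((e1.ci_high - r1) ** 2 + (r2 - e2.ci_low) ** 2)
    return DifferenceEstimate(
        delta=delta, ci_low=lo, ci_high=hi, n1=e1.n, n2=e2.n, level=level
    )


def fold_changes(pv: PairedValues) -> np.ndarray:
    """Within-pair fold change, larger value over smaller (all >= 1).

    Putting the larger value in the numerator makes medians of the ratio
    comparable across sets (unrestricted ratios of symmetric pairs would
    all have medians near one). Exactly invariant to pair orientation.
    """
    _check_positive(pv)
    hi = np.maximum(pv.first, pv.second)
    lo = np.minimum(pv.first, pv.second)
    return hi / lo


def log_fold_changes(pv: PairedValues, base: float | str = "e") -> np.ndarray:
    """Logarithm of the within-pair ratio ``first/second``.

    No numerator restriction is needed: for symmetric pairs the
    distribution is symmetric around 0, and its standard deviation is
    orientation-invariant. The log base (default natural) scales the
    result and is recorded by callers alongside any summary.
    """
    _check_positive(pv)
    raw = np.log(pv.first) - np.log(pv.second)
    if base == "e":
        return raw
    return raw / math.log(float(base))


def _check_positive(pv: PairedValues) -> None:
    bad = (pv.first <= 0) | (pv.second <= 0)
    if bad.any():
        pair = pv.pair_ids[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-positive {pv.parameter!r} value in pair {pair}")


@dataclass(frozen=True)
class BootstrapInterval:
    """A bootstrap confidence interval around a point estimate."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: str
    method: str
    n: int
    reps: int
    level: float
    seed: int | None


_STAT_FUNCS = {
    "median": lambda a, axis: np.median(a, axis=axis),
    "sd": lambda a, axis: np.std(a, axis=axis, ddof=1),
}


def _resolve_statistic(statistic: str, n: int):
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}; expected 'median' or 'sd'")
    if statistic == "sd" and n < 2:
        raise ValueError("sd needs at least two observations")
    return _STAT_FUNCS[statistic]


def bootstrap_statistic_ci(
    values: Sequence[float],
    statistic: str = "median",
    reps: int = 2000,
    method: str = "normal",
    level: float = 0.95,
    seed: int | None = 0,
) -> BootstrapInterval:
    """Bootstrap CI for the median or standard deviation of a sample.

    The point estimate is computed on the full sample. ``normal`` uses
    ``estimate ± z * sd(bootstrap replicates)``; ``percentile`` takes the
    empirical ``alpha/2`` and ``1 - alpha/2`` quantiles of the replicates.
    Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    func = _resolve_statistic(statistic, n)
    estimate = float(func(values, None))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boot = func(values[idx], 1)
    lo, hi = _interval_from_replicates(estimate, boot, method, level)
    return BootstrapInterval(
        estimate=estimate, ci_low=lo, ci_high=hi, statistic=statistic,
        method=method, n=n, reps=reps, level=level, seed=seed,
    )


def bootstrap_difference_ci(
    values_a: Sequence[float],
    values_b: Sequence[float],
    statistic: str = "median",
    reps: int = 2000,
    method: str = "normal",
    level: float = 0.95,
    seed: int | None = 0,
) -> BootstrapInterval:
    """Bootstrap CI for ``statistic(a) - statistic(b)``, independent groups.

    Every replicate resamples both groups independently. Swapping the
    arguments negates the point estimate and mirrors the interval.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    func_a = _resolve_statistic(statistic, len(a))
    func_b = _resolve_statistic(statistic, len(b))
    estimate = float(func_a(a, None) - func_b(b, None))
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(a), size=(reps, len(a)))
    idx_b = rng.integers(0, len(b), size=(reps, len(b)))
    boot = func_a(a[idx_a], 1) - func_b(b[idx_b], 1)
    lo, hi = _interval_from_replicates(estimate, boot, method, level)
    return BootstrapInterval(
        estimate=estimate, ci_low=lo, ci_high=hi, statistic=statistic,
        method=method, n=min(len(a), len(b)), reps=reps, level=level, seed=seed,
    )


def _interval_from_replicates(
    estimate: float, boot: np.ndarray, method: str, level: float
) -> tuple[float, float]:
    alpha = 1 - level
    if method == "normal":
        z = sps.norm.ppf(1 - alpha / 2)
        se = float(np.std(boot, ddof=1)) if len(boot) > 1 else 0.0
        return estimate - z * se, estimate + z * se
    if method == "percentile":
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown bootstrap method {method!r}")
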