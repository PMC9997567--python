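"""From-formula statistics for fluctuation analysis.

Everything here is computed directly from its defining formula (rank-based
correlations with mid-rank ties, the Brown-Forsythe median-centered
equality-of-variance test, cumulative log-log mutant-count distributions
and their fitted slope, exact Poisson tails).  scipy supplies only the
reference distributions for p-values (F, t, normal); the statistics
themselves are hand-computed so that every number in a fluctuation summary
is traceable to its formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "FluctuationSummary",
    "summarize_counts",
    "cumulative_proportions",
    "loglog_slope",
    "poisson_tail",
    "brown_forsythe",
    "spearman_rho",
    "kendall_tau",
    "jackpot_plates",
    "variance_ratio",
    "summarize_fluctuation",
]


def _as_array(counts: Sequence[float], name: str = "counts") -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return arr


def summarize_counts(counts: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample variance (n-1 denominator) and median of plate counts.

    With a single observation the variance is undefined and returned as NaN.
    """
    arr = _as_array(counts)
    mean = float(arr.sum() / arr.size)
    if arr.size < 2:
        variance = float("nan")
    else:
        variance = float(((arr - mean) ** 2).sum() / (arr.size - 1))
    median = float(np.median(arr))
    return mean, variance, median


def cumulative_proportions(counts: Sequence[float]) -> list[tuple[int, float]]:
    """Points ``(x, P(X >= x))`` for x = 1 .. max observed, keeping only
    x with positive proportion — the construction used for cumulative
    log-log mutant-count plots."""
    arr = _as_array(counts)
    x_max = int(arr.max())
    points = []
    for x in range(1, x_max + 1):
        p = float((arr >= x).mean())
        if p > 0:
            points.append((x, p))
    return points


def loglog_slope(points: Sequence[tuple[float, float]]) -> float:
    """OLS slope of log10(proportion) on log10(x).

    A Poisson-like (narrow) count distribution drops steeply; a
    Luria-Delbrueck (jackpot) distribution is close to a straight shallow
    line.
    """
    pts = [(x, p) for x, p in points if x >= 1 and p > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 usable points for a slope")
    lx = np.log10([x for x, _ in pts])
    ly = np.log10([p for _, p in pts])
    lx_c = lx - lx.mean()
    return float((lx_c * (ly - ly.mean())).sum() / (lx_c**2).sum())


def poisson_tail(lambda_: float, x: int) -> float:
    """Exact upper tail ``P(X >= x)`` for X ~ Poisson(lambda)."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if x <= 0:
        return 1.0
    # 1 - sum_{k<x} e^-lam lam^k / k!, accumulated in log-safe form
    term = math.exp(-lambda_)
    cdf = term
    for k in range(1, x):
        term *= lambda_ / k
        cdf += term
    return max(0.0, 1.0 - cdf)


def brown_forsythe(
    *groups: Sequence[float],
    method: str = "f",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Brown-Forsythe equality-of-variance test.

    Deviations are taken from the group medians, ``z_ij = |y_ij - med_j|``,
    and the one-way ANOVA F statistic of the z values is referred to the
    F(p-1, N-p) distribution (``method="f"``) or to a label-permutation
    null (``method="permutation"``, >= 1e4 permutations recommended).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ys = [_as_array(g, "group") for g in groups]
    if any(y.size < 2 for y in ys):
        raise ValueError("every group needs at least 2 observations")

    def f_stat(ys: list[np.ndarray]) -> float:
        zs = [np.abs(y - np.median(y)) for y in ys]
        all_z = np.concatenate(zs)
        grand = all_z.mean()
        p = len(zs)
        n_total = all_z.size
        between = sum(z.size * (z.mean() - grand) ** 2 for z in zs)
        within = sum(((z - z.mean()) ** 2).sum() for z in zs)
        if within == 0:
            return 0.0 if between == 0 else float("inf")
        return float(((n_total - p) / (p - 1)) * between / within)

    f_obs = f_stat(ys)
    p_groups = len(ys)
    n_total = sum(y.size for y in ys)
    if method == "f":
        if f_obs == 0.0:
            return 0.0, 1.0
        if math.isinf(f_obs):
            return f_obs, 0.0
        p_value = float(_sps.f.sf(f_obs, p_groups - 1, n_total - p_groups))
        return f_obs, p_value
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(ys)
        sizes = [y.size for y in ys]
        exceed = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            parts, start = [], 0
            for s in sizes:
                parts.append(pooled[start : start + s])
                start += s
            if f_stat(parts) >= f_obs:
                exceed += 1
        return f_obs, (1 + exceed) / (1 + n_permutations)
    raise ValueError(f"unknown method {method!r}")


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sorted_x = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _check_paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    return xa, ya


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    rho is the Pearson correlation of the mid-ranks; the two-sided p-value
    uses the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2
    degrees of freedom.
    """
    xa, ya = _check_paired(x, y)
    rx, ry = _midranks(xa), _midranks(ya)
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho = float((rx_c * ry_c).sum() / denom)
    n = xa.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return rho, p


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with tie correction; p-value by normal approximation.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D count concordant
    and discordant pairs and n1, n2 are tie corrections in x and y.
    """
    xa, ya = _check_paired(x, y)
    n = xa.size
    dx = np.sign(xa[:, None] - xa[None, :])
    dy = np.sign(ya[:, None] - ya[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    concordant = int((prod > 0).sum())
    discordant = int((prod < 0).sum())
    s = concordant - discordant

    def tie_sizes(a: np.ndarray) -> np.ndarray:
        _, counts = np.unique(a, return_counts=True)
        return counts[counts > 1].astype(float)

    tx, ty = tie_sizes(xa), tie_sizes(ya)
    n0 = n * (n - 1) / 2.0
    n1 = float((tx * (tx - 1) / 2.0).sum())
    n2 = float((ty * (ty - 1) / 2.0).sum())
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise ValueError("constant input: rank correlation undefined")
    tau = s / denom

    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = float((ty * (ty - 1) * (2 * ty + 5)).sum())
    v1 = float((tx * (tx - 1)).sum() * (ty * (ty - 1)).sum()) / (2.0 * n * (n - 1))
    v2 = (
        float((tx * (tx - 1) * (tx - 2)).sum() * (ty * (ty - 1) * (ty - 2)).sum())
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        return tau, 1.0
    z = s / math.sqrt(var_s)
    p = float(2.0 * _sps.norm.sf(abs(z)))
    return tau, min(1.0, p)


def jackpot_plates(
    counts: Sequence[float], multiplier: float = 5.0
) -> list[int]:
    """Indices of jackpot plates.

    A plate is flagged when its count exceeds
    ``median + multiplier * max(1, IQR)``.  The cutoff rule is a
    convention (configurable via ``multiplier``), chosen so that the
    extreme counts of a fluctuation test's parallel arm are flagged while
    single-culture plates never are.
    """
    arr = _as_array(counts)
    median = float(np.median(arr))
    q1, q3 = np.percentile(arr, [25, 75])
    threshold = median + multiplier * max(1.0, float(q3 - q1))
    return [int(i) for i in np.nonzero(arr > threshold)[0]]


def variance_ratio(
    between_counts: Sequence[float], within_counts: Sequence[float]
) -> float:
    """Fold-ratio of between-culture to within-culture sample variance."""
    _, var_b, _ = summarize_counts(between_counts)
    _, var_w, _ = summarize_counts(within_counts)
    if not var_w > 0:
        raise ValueError(
            "within-culture variance is zero; the fold ratio is undefined"
        )
    return var_b / var_w


@dataclass
class FluctuationSummary:
    """Distribution summary of revertant counts per plate."""

    mean: float
    variance: float
    median: float
    jackpot_indices: list[int] = field(default_factory=list)
    cumulative_points: list[tuple[int, float]] = field(default_factory=list)
    loglog_slope: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "variance": self.variance,
            "median": self.median,
            "jackpot_indices": self.jackpot_indices,
            "cumulative_points": self.cumulative_points,
            "loglog_slope": self.loglog_slope,
        }


def summarize_fluctuation(
    counts: Sequence[float], jackpot_multiplier: float = 5.0
) -> FluctuationSummary:
    """Full :class:`FluctuationSummary` of one arm of a fluctuation test."""
    mean, variance, median = summarize_counts(counts)
    points = cumulative_proportions(counts) if np.asarray(counts).max() >= 1 else []
    slope = None
    usable = [(x, p) for x, p in points if p > 0]
    if len(usable) >= 2:
        slope = loglog_slope(usable)
    return FluctuationSummary(
        mean=mean,
        variance=variance,
        median=median,
        jackpot_indices=jackpot_plates(counts, jackpot_multiplier),
        cumulative_points=points,
        loglog_slope=slope,
    )
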