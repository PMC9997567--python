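"""Plots for reversion timelines and fluctuation distributions."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .selection import ReversionAssayResult
from .stats import cumulative_proportions, loglog_slope


def plot_reversion_accumulation(result: ReversionAssayResult, ax=None):
    """Revertant frequency (log scale) and lawn size versus day."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    positive = result.frequency > 0
    ax.semilogy(result.days[positive], result.frequency[positive], "r^-",
                label="revertant frequency")
    ax.set_xlabel("day of selective incubation")
    ax.set_ylabel("revertant colonies per plated cell")
    ax.legend()
    return ax


def plot_cumulative_loglog(counts_by_label: dict[str, Sequence[int]], ax=None):
    """Cumulative log-log mutant-count distributions with fitted slopes.

    Narrow (Poisson-like) arms drop steeply; jackpot (Luria-Delbrueck)
    arms approach a shallow straight line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, counts in counts_by_label.items():
        points = cumulative_proportions(counts)
        if not points:
            continue
        xs = np.array([x for x, _ in points], dtype=float)
        ps = np.array([p for _, p in points])
        try:
            slope = loglog_slope(points)
            label = f"{label} (slope {slope:.2f})"
        except ValueError:
            pass
        ax.loglog(xs, ps, "o-", label=label)
    ax.set_xlabel("x (revertants per plate)")
    ax.set_ylabel("proportion of plates with >= x")
    ax.legend()
    return ax
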