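"""Domain types and the two elementary stochastic events of the model.

A tandem amplification is described by its repeated unit (the *amplicon*)
and its copy number.  Two events drive copy-number dynamics:

* duplication formation: a haploid cell acquires a tandem duplication
  (1 -> 2 copies) with probability ``k_dup`` per division;
* unequal sister-chromosome exchange: a cell with ``n >= 2`` tandem copies
  carries ``n - 1`` repeat junctions and undergoes an exchange with
  probability ``k_rec * (n - 1)`` per division, producing daughters with
  ``n + d`` and ``n - d`` copies (``d`` uniform on ``1..n-1``).  The same
  event class both amplifies (selected daughter) and collapses the array.

Selective growth is copy-number dependent: haploids cannot grow on benzoate
(``g(1) = 0``) and growth saturates at ``g_max`` divisions/day with rising
copy number.  Without selection, extra copies carry a fitness cost that
scales with the amount of amplified DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import RateConfig

__all__ = [
    "AmpliconSpec",
    "CellClass",
    "Population",
    "growth_rate",
    "nonselective_fitness",
    "copy_step_kernel",
]


@dataclass(frozen=True)
class AmpliconSpec:
    """The repeated chromosomal unit of a tandem amplification.

    ``length_kb`` is the physical length of the repeat (12-290 kb in this
    system).  ``spans_noti_site`` records whether the repeat crosses the
    NotI site between the E and D fragments (which determines the diagnostic
    digestion pattern).  ``permissive`` records whether the duplication's
    endpoints permit selectable amplification; it is fixed at creation
    (the class is frozen).
    """

    length_kb: float
    spans_noti_site: bool = False
    permissive: bool = True

    MIN_KB = 12.0
    MAX_KB = 290.0

    def __post_init__(self) -> None:
        if not self.MIN_KB <= self.length_kb <= self.MAX_KB:
            raise ValueError(
                f"amplicon length must lie in [{self.MIN_KB}, {self.MAX_KB}] kb, "
                f"got {self.length_kb!r}"
            )


@dataclass
class CellClass:
    """Cells sharing a copy number and amplicon.

    ``count`` is real-valued so that very large classes can be tracked
    deterministically in expectation; ``amplicon`` is meaningless (None)
    for haploids.
    """

    copy_number: int
    count: float
    amplicon: Optional[AmpliconSpec] = None

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.copy_number >= 2 and self.amplicon is None:
            raise ValueError("amplified classes need an amplicon")


@dataclass
class Population:
    """A collection of cell classes, at most one per (copy number, amplicon)."""

    classes: list[CellClass] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._merge()

    def _merge(self) -> None:
        merged: dict[tuple[int, Optional[AmpliconSpec]], CellClass] = {}
        for c in self.classes:
            key = (c.copy_number, c.amplicon if c.copy_number >= 2 else None)
            if key in merged:
                merged[key].count += c.count
            else:
                merged[key] = CellClass(c.copy_number, c.count, c.amplicon)
        self.classes = list(merged.values())

    def total(self) -> float:
        return float(sum(c.count for c in self.classes))

    def duplication_count(self) -> float:
        return float(sum(c.count for c in self.classes if c.copy_number >= 2))

    def duplication_frequency(self) -> float:
        total = self.total()
        return self.duplication_count() / total if total > 0 else 0.0

    def __iter__(self):
        return iter(self.classes)


def growth_rate(copy_number: int, config: RateConfig) -> float:
    """Divisions per day on selective medium for a cell with ``copy_number``
    tandem copies.

    Zero for haploids, strictly increasing in copy number, saturating at
    ``g_max``:  ``g(n) = g_max * x**h / (x**h + k_half**h)`` with
    ``x = n - 1`` and Hill exponent ``h``.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    x = float(copy_number - 1)
    if x == 0.0:
        return 0.0
    xh = x**config.hill
    return config.g_max * xh / (xh + config.k_half**config.hill)


def nonselective_fitness(
    copy_number: int, amplicon: Optional[AmpliconSpec], config: RateConfig
) -> float:
    """Relative fitness (vs haploid) without selection.

    ``1 - dup_cost_per_copy * (n - 1) * length_kb / 28``, floored at 0;
    the cost is normalized to the 28 kb reference amplicon.  Haploids have
    fitness exactly 1.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    if copy_number == 1:
        return 1.0
    if amplicon is None:
        raise ValueError("amplified cells need an amplicon")
    cost = (
        config.dup_cost_per_copy
        * (copy_number - 1)
        * amplicon.length_kb
        / config.ref_amplicon_kb
    )
    return max(0.0, 1.0 - cost)


def copy_step_kernel(
    copy_number: int,
    rng: np.random.Generator,
    config: RateConfig,
    forced_maximal: bool = False,
) -> tuple[int, int]:
    """One division of one cell: returns the pair of daughter copy numbers.

    For ``n = 1`` there is no repeat substrate and the result is always
    ``(1, 1)``.  For ``n >= 2`` an unequal exchange occurs with probability
    ``min(1, k_rec * (n - 1))``; the exchange offset ``d`` is uniform on
    ``1..n-1`` (or always ``n - 1`` with ``forced_maximal``, which makes
    the selected-daughter trajectory 2, 3, 5, 9, 17, ...).  Daughter copy
    numbers always sum to ``2 n``.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    n = copy_number
    if n == 1:
        return (1, 1)
    p_exchange = min(1.0, config.k_rec * (n - 1))
    if rng.random() >= p_exchange:
        return (n, n)
    d = n - 1 if forced_maximal else int(rng.integers(1, n))
    return (n + d, n - d)


def make_amplicon(
    length_kb: float, *, permissive: bool = True, spans_noti_site: bool | None = None
) -> AmpliconSpec:
    """Convenience constructor; infers ``spans_noti_site`` (False for short
    amplicons confined within the 197 kb E fragment) when not given."""
    if spans_noti_site is None:
        spans_noti_site = length_kb > 197.0
    return AmpliconSpec(
        length_kb=length_kb, spans_noti_site=spans_noti_site, permissive=permissive
    )
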