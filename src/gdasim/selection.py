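"""Selective-plate dynamics: clone expansion, lawn trajectory, reversion assay.

On a benzoate plate the haploid lawn cannot grow; clones founded by plated
duplication-bearing cells expand at copy-number-dependent rates while
unequal exchanges step their copy number up and down.  A clone becomes a
visible colony on the first day its cumulative size reaches ``n_vis``.
Under the default (pre-existence) model no new duplications arise on the
plate; the explicit "adaptive" contrast model (``plate_induction_rate > 0``)
induces duplications in the lawn at a constant per-cell per-day rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._engine import CloneBatch
from .config import RateConfig
from .core import AmpliconSpec, Population
from .nonselective import sample_amplicon, simulate_culture, sample_plated_cells

__all__ = [
    "ColonyRecord",
    "PlateTimeline",
    "ReversionAssayResult",
    "lawn_dynamics",
    "simulate_clone",
    "simulate_clones",
    "simulate_plate",
    "run_reversion_assay",
]


@dataclass
class ColonyRecord:
    appearance_day: int
    founder_copy_number: int
    amplicon: AmpliconSpec
    final_modal_copy_number: int


@dataclass
class PlateTimeline:
    """Daily state of one selective plate (day index is 1-based)."""

    days: np.ndarray  # 1..D
    visible_colonies: np.ndarray  # cumulative visible clones per day
    lawn_viable: np.ndarray  # deterministic lawn trajectory
    colony_records: list[ColonyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.visible_colonies) < 0):
            raise ValueError("visible_colonies must be non-decreasing")
        if np.any(self.lawn_viable <= 0):
            raise ValueError("lawn_viable must stay positive")


def lawn_dynamics(day: float, config: RateConfig) -> float:
    """Viable haploid lawn count on a selective plate.

    Deterministic piecewise-geometric trajectory: ``n_plate`` at day 0,
    decline to ``n_plate / lawn_decline_fold`` at day 12, recovery to
    ``n_plate`` at day 21, constant thereafter.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    n0 = config.n_plate
    fold = config.lawn_decline_fold
    if day <= 12:
        return n0 * fold ** (-day / 12.0)
    if day <= 21:
        return (n0 / fold) * fold ** ((day - 12.0) / 9.0)
    return n0


def simulate_clones(
    founder_copy_number: int,
    amplicon: AmpliconSpec,
    days: float,
    config: RateConfig,
    n_clones: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, CloneBatch]:
    """Simulate ``n_clones`` i.i.d. clones from single founder cells;
    returns (appearance days with NaN = not visible, the batch)."""
    if founder_copy_number < 2:
        raise ValueError("haploids cannot initiate selective clones")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founders = np.full(n_clones, founder_copy_number, dtype=np.int64)
    growing = np.full(n_clones, bool(amplicon.permissive))
    batch = CloneBatch(founders, config, rng, growing=growing)
    appearance = batch.run(days)
    return appearance, batch


def simulate_clone(
    founder_copy_number: int,
    amplicon: AmpliconSpec,
    days: float,
    config: RateConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[Optional[int], dict[int, float]]:
    """One clone on a selective plate.

    Returns ``(appearance_day or None, final copy-number distribution)``.
    The final distribution retains lower-copy ancestor classes: clones are
    heterogeneous populations, not pure high-copy cells.
    """
    appearance, batch = simulate_clones(
        founder_copy_number, amplicon, days, config, 1, seed
    )
    dist = {
        int(n): float(batch.counts[0, n])
        for n in np.nonzero(batch.counts[0, 1:])[0] + 1
    }
    day = appearance[0]
    return (None if math.isnan(day) else int(day)), dist


def _empty_timeline(days: int, config: RateConfig) -> PlateTimeline:
    day_axis = np.arange(1, days + 1)
    return PlateTimeline(
        days=day_axis,
        visible_colonies=np.zeros(days, dtype=np.int64),
        lawn_viable=np.array([lawn_dynamics(d, config) for d in day_axis]),
    )


def simulate_plate(
    inoculum: Population,
    days: int,
    config: RateConfig,
    seed: int | np.random.Generator | None = None,
) -> PlateTimeline:
    """Simulate one selective plate seeded with ``inoculum``.

    Every permissive duplication-bearing founder cell initiates an explicit
    stochastic clone; non-permissive and haploid cells never grow.  Under
    the adaptive contrast model additional duplication clones are induced
    in the lawn each day at ``plate_induction_rate`` per cell per day.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if not inoculum.classes:
        raise ValueError("inoculum must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    founders: list[int] = []
    amplicons: list[AmpliconSpec] = []
    for c in inoculum:
        if c.copy_number < 2 or c.amplicon is None or not c.amplicon.permissive:
            continue
        k = int(round(c.count))
        founders.extend([c.copy_number] * k)
        amplicons.extend([c.amplicon] * k)

    timeline = _empty_timeline(days, config)
    cohorts: list[tuple[float, np.ndarray, list[AmpliconSpec]]] = []
    if founders:
        cohorts.append((0.0, np.asarray(founders, dtype=np.int64), amplicons))

    if config.plate_induction_rate > 0:
        # adaptive contrast: constant per-day induction in the (fixed) lawn
        for day in range(1, days + 1):
            mean = config.plate_induction_rate * lawn_dynamics(day - 1, config)
            k = int(rng.poisson(mean))
            if k:
                amps = [sample_amplicon(rng, config) for _ in range(k)]
                keep = [a for a in amps if a.permissive]
                if keep:
                    cohorts.append(
                        (float(day - 1), np.full(len(keep), 2, dtype=np.int64), keep)
                    )

    appearance_all: list[np.ndarray] = []
    records: list[ColonyRecord] = []
    for start, f, amps in cohorts:
        batch = CloneBatch(f, config, rng)
        appearance = batch.run(days - start) + start
        appearance_all.append(appearance)
        modal = batch.modal_copy_numbers()
        for i in range(f.size):
            if not math.isnan(appearance[i]):
                records.append(
                    ColonyRecord(
                        appearance_day=int(math.ceil(appearance[i] - 1e-9)),
                        founder_copy_number=int(f[i]),
                        amplicon=amps[i],
                        final_modal_copy_number=int(modal[i]),
                    )
                )

    if appearance_all:
        appeared = np.concatenate(appearance_all)
        appeared = appeared[~np.isnan(appeared)]
        for day in timeline.days:
            timeline.visible_colonies[day - 1] = int((appeared <= day).sum())
    timeline.colony_records = sorted(records, key=lambda r: r.appearance_day)
    return timeline


@dataclass
class ReversionAssayResult:
    """Per-day revertant frequencies averaged over replicate plates."""

    days: np.ndarray
    counts: np.ndarray  # plates x days cumulative visible colonies
    frequency: np.ndarray  # mean colonies per plated cell per day
    timelines: list[PlateTimeline]


def run_reversion_assay(
    config: RateConfig,
    n_plates: int,
    seed: int | None = None,
    days: int = 21,
) -> ReversionAssayResult:
    """The Ben reversion assay: independent culture -> plate per replicate.

    frequency(day) = cumulative visible colonies / plated cells, averaged
    over plates.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    ss = np.random.SeedSequence(seed)
    counts = np.zeros((n_plates, days), dtype=np.int64)
    timelines: list[PlateTimeline] = []
    for i, child in enumerate(ss.spawn(n_plates)):
        rng = np.random.default_rng(child)
        culture = simulate_culture(config.culture_final_size, config, rng)
        inoculum = sample_plated_cells(culture, config.n_plate, rng)
        timeline = simulate_plate(inoculum, days, config, rng)
        counts[i] = timeline.visible_colonies
        timelines.append(timeline)
    frequency = counts.mean(axis=0) / config.n_plate
    return ReversionAssayResult(
        days=np.arange(1, days + 1),
        counts=counts,
        frequency=frequency,
        timelines=timelines,
    )
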