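"""Nonselective liquid-culture growth and the precursor duplication structure.

A culture grows from a single haploid founder by discrete non-overlapping
generations.  Each generation every cell divides; haploid divisions spawn
new duplication lineages with probability ``k_dup``; duplication-bearing
classes undergo unequal sister-chromosome exchanges (``k_rec`` per repeat
junction per division) which both amplify and collapse the array, and pay
the configured nonselective fitness cost.  Each duplication event founds a
lineage with its own sampled amplicon, so a saturated culture carries the
between-culture jackpot variability of a fluctuation test: an early event
leaves a large clone, a late one a few cells.

The analytic source/loss balance ``f* = k_dup / (k_loss_eff + cost)`` is the
closed-form check on the simulator.  Note the relaxation time towards f* is
``1/(k_loss_eff + cost)`` divisions; with the default rates (loss ~1e-2)
an overnight culture (~30 generations) is still in the transient regime and
carries a duplication frequency of roughly ``k_dup * generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import RateConfig
from .core import AmpliconSpec, CellClass, Population, nonselective_fitness

__all__ = [
    "CultureResult",
    "steady_state_duplication_frequency",
    "expected_transient_frequency",
    "sample_amplicon",
    "simulate_culture",
    "sample_plated_cells",
]

#: weight applied to k_rec when it acts as the effective duplication loss
#: rate in the analytic steady state.  An unequal exchange in a 2-copy cell
#: returns one daughter to haploidy; counting every junction-driven exchange
#: as a loss of the duplicated state gives weight 1.
COLLAPSE_WEIGHT = 1.0


@dataclass
class CultureResult:
    """A saturated nonselective culture."""

    population: Population
    n_generations: int
    duplication_frequency: float
    founder_event_generation: Optional[int]


def steady_state_duplication_frequency(
    config: RateConfig, k_loss_effective: float | None = None
) -> float:
    """Analytic balance frequency ``f* = k_dup / (k_loss_eff + cost)``.

    ``k_loss_eff`` defaults to ``COLLAPSE_WEIGHT * k_rec`` and the cost term
    is ``dup_cost_per_copy`` (the per-extra-copy cost of a reference-length
    duplication).  With the default rates (1e-6 formation, 1e-2 loss, zero
    cost) this is 1e-4, i.e. 0.01%.
    """
    if k_loss_effective is None:
        k_loss_effective = COLLAPSE_WEIGHT * config.k_rec
    denom = k_loss_effective + config.dup_cost_per_copy
    if denom <= 0:
        raise ValueError("no steady state: effective loss + cost must be positive")
    return config.k_dup / denom


def expected_transient_frequency(
    config: RateConfig, n_generations: int, k_loss_effective: float | None = None
) -> float:
    """Deterministic expectation of the duplication frequency after a finite
    number of generations, ``f(t) = f* (1 - (1 - k_loss)**t)`` — the
    independent oracle for the simulator mean at default (slow-relaxing)
    rates."""
    if k_loss_effective is None:
        k_loss_effective = COLLAPSE_WEIGHT * config.k_rec
    f_star = steady_state_duplication_frequency(config, k_loss_effective)
    decay = k_loss_effective + config.dup_cost_per_copy
    return f_star * (1.0 - (1.0 - decay) ** n_generations)


def sample_amplicon(rng: np.random.Generator, config: RateConfig) -> AmpliconSpec:
    """Draw a random amplicon.

    Length is log-uniform on [12, 290] kb.  ``permissive`` is true with
    probability ``permissive_fraction`` (the endpoint-restriction rule).
    The repeat spans the NotI site between the E and D fragments with
    probability ``min(1, L/197)``: one amplicon end is pinned near the cat
    cluster inside the 197 kb E fragment, so longer repeats are more likely
    to cross the boundary.
    """
    lo, hi = math.log(config.amplicon_min_kb), math.log(config.amplicon_max_kb)
    length = float(math.exp(rng.uniform(lo, hi)))
    permissive = bool(rng.random() < config.permissive_fraction)
    spans = bool(rng.random() < min(1.0, length / 197.0))
    return AmpliconSpec(length_kb=length, spans_noti_site=spans, permissive=permissive)


# ---------------------------------------------------------------------------


class _LineageTable:
    """Growable per-lineage copy-number counts plus amplicon metadata."""

    def __init__(self, nmax: int) -> None:
        cap = 256
        self.nmax = nmax
        self.counts = np.zeros((cap, nmax + 1))
        self.length_kb = np.zeros(cap)
        self.permissive = np.zeros(cap, dtype=bool)
        self.spans = np.zeros(cap, dtype=bool)
        self.founded_gen = np.zeros(cap, dtype=np.int64)
        self.n = 0

    def add(self, amplicons: list[AmpliconSpec], generation: int) -> None:
        k = len(amplicons)
        while self.n + k > self.counts.shape[0]:
            grow = self.counts.shape[0]
            self.counts = np.vstack([self.counts, np.zeros((grow, self.nmax + 1))])
            for name in ("length_kb",):
                self.length_kb = np.concatenate([self.length_kb, np.zeros(grow)])
            self.permissive = np.concatenate([self.permissive, np.zeros(grow, bool)])
            self.spans = np.concatenate([self.spans, np.zeros(grow, bool)])
            self.founded_gen = np.concatenate(
                [self.founded_gen, np.zeros(grow, np.int64)]
            )
        for i, amp in enumerate(amplicons):
            j = self.n + i
            self.counts[j, 2] = 1.0
            self.length_kb[j] = amp.length_kb
            self.permissive[j] = amp.permissive
            self.spans[j] = amp.spans_noti_site
            self.founded_gen[j] = generation
        self.n += k


def _advance_lineages(
    table: _LineageTable, config: RateConfig, rng: np.random.Generator
) -> float:
    """One synchronous generation for all duplication lineages.

    Every cell divides; exchanges redistribute copy number; daughters pay
    the nonselective fitness cost as a survival probability.  Returns the
    number of cells collapsed to haploidy (they rejoin the bulk).
    """
    if table.n == 0:
        return 0.0
    C = table.counts[: table.n]
    rows, cols = np.nonzero(C[:, 2:])
    if rows.size == 0:
        return 0.0
    cols = cols + 2
    c = C[rows, cols]
    q = np.minimum(1.0, config.k_rec * (cols - 1.0))
    cost = config.dup_cost_per_copy * (cols - 1) * table.length_kb[rows] / config.ref_amplicon_kb
    w = np.clip(1.0 - cost, 0.0, 1.0)

    c_int = np.floor(c)
    c_frac = c - c_int
    stoch = c < config.stochastic_threshold

    E_int = np.zeros_like(c)
    if stoch.any():
        E_int[stoch] = rng.binomial(c_int[stoch].astype(np.int64), q[stoch])
    E_det = np.where(stoch, c_frac * q, c * q)

    # same-class daughters (two per non-exchanging division), thinned by w
    S_int = np.zeros_like(c)
    if stoch.any():
        n_same = 2.0 * (c_int[stoch] - E_int[stoch])
        S_int[stoch] = rng.binomial(n_same.astype(np.int64), w[stoch])
    S_det = np.where(stoch, 2.0 * c_frac * (1 - q) * w, 2.0 * c * (1 - q) * w)

    # intrachromosomal deletions among the surviving same-class daughters
    r_i = np.minimum(1.0, config.intra_collapse_weight * config.k_rec * (cols - 1.0))
    I_int = np.zeros_like(c)
    if stoch.any():
        I_int[stoch] = rng.binomial(S_int[stoch].astype(np.int64), r_i[stoch])
    I_det = S_det * r_i
    C[rows, cols] = S_int - I_int + S_det - I_det

    nmax = table.nmax
    ic = I_int > 0
    if ic.any():
        reps = I_int[ic].astype(np.int64)
        ic_rows = np.repeat(rows[ic], reps)
        ic_n = np.repeat(cols[ic], reps)
        d = (rng.random(ic_n.size) * (ic_n - 1)).astype(np.int64) + 1
        np.add.at(C, (ic_rows, ic_n - d), 1.0)
    im = I_det > 0
    if im.any():
        for n_col in np.unique(cols[im]):
            sel = im & (cols == n_col)
            r = rows[sel]
            v = I_det[sel] / (n_col - 1)
            C[r, 1:n_col] += v[:, None]
    # stochastic exchange daughters
    ex = E_int > 0
    if ex.any():
        reps = E_int[ex].astype(np.int64)
        ex_rows = np.repeat(rows[ex], reps)
        ex_n = np.repeat(cols[ex], reps)
        ex_w = np.repeat(w[ex], reps)
        d = (rng.random(ex_n.size) * (ex_n - 1)).astype(np.int64) + 1
        up = np.minimum(ex_n + d, nmax)
        down = ex_n - d
        keep_up = rng.random(ex_n.size) < ex_w
        keep_down = rng.random(ex_n.size) < ex_w
        if keep_up.any():
            np.add.at(C, (ex_rows[keep_up], up[keep_up]), 1.0)
        if keep_down.any():
            np.add.at(C, (ex_rows[keep_down], down[keep_down]), 1.0)

    # deterministic exchange mass
    dm = E_det > 0
    if dm.any():
        for n_col in np.unique(cols[dm]):
            sel = dm & (cols == n_col)
            r = rows[sel]
            v = E_det[sel] * w[sel] / (n_col - 1)
            hi = min(2 * n_col - 1, nmax)
            C[r, 1 : hi + 1] += v[:, None]
            C[r, n_col] -= v
            overflow = (2 * n_col - 1) - nmax
            if overflow > 0:
                C[r, nmax] += v * overflow

    collapsed = float(C[: table.n, 1].sum())
    C[: table.n, 1] = 0.0
    return collapsed


def simulate_culture(
    final_size: float,
    config: RateConfig,
    seed: int | np.random.Generator | None = None,
) -> CultureResult:
    """Grow one nonselective culture from a single haploid founder.

    Runs ``ceil(log2(final_size))`` synchronous generations.  The haploid
    bulk is advanced deterministically; duplication lineages are tracked
    explicitly (stochastic below ``stochastic_threshold`` cells).  Same
    (config, seed) always yields the identical result.
    """
    if final_size < 1:
        raise ValueError("final_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    generations = max(1, math.ceil(math.log2(final_size)))
    table = _LineageTable(config.max_copy_number)
    n_haploid = 1.0
    for gen in range(1, generations + 1):
        collapsed = _advance_lineages(table, config, rng)
        new_events = 0
        if config.k_dup > 0 and n_haploid > 0:
            # each of the 2*N haploid daughters independently acquires a
            # duplication with probability k_dup, so that the per-generation
            # frequency gain is k_dup and the balance with per-division
            # collapse (k_rec per junction) is f* = k_dup / k_rec
            mean_events = 2.0 * config.k_dup * n_haploid
            new_events = int(rng.poisson(mean_events))
        n_haploid = 2.0 * n_haploid - new_events + collapsed
        if new_events:
            amps = [sample_amplicon(rng, config) for _ in range(new_events)]
            table.add(amps, gen)

    dup_counts = table.counts[: table.n]
    dup_total = float(dup_counts[:, 2:].sum())
    total = n_haploid + dup_total
    freq = dup_total / total if total > 0 else 0.0

    classes = [CellClass(1, n_haploid)]
    surviving_gens = []
    for j in range(table.n):
        row = dup_counts[j]
        if row[2:].sum() <= 0:
            continue
        surviving_gens.append(int(table.founded_gen[j]))
        amp = AmpliconSpec(
            length_kb=float(table.length_kb[j]),
            spans_noti_site=bool(table.spans[j]),
            permissive=bool(table.permissive[j]),
        )
        for n_copy in np.nonzero(row[2:])[0] + 2:
            classes.append(CellClass(int(n_copy), float(row[n_copy]), amp))

    return CultureResult(
        population=Population(classes),
        n_generations=generations,
        duplication_frequency=freq,
        founder_event_generation=min(surviving_gens) if surviving_gens else None,
    )


def sample_plated_cells(
    culture: CultureResult,
    n_plate: float,
    seed: int | np.random.Generator | None = None,
) -> Population:
    """Draw one plate inoculum from a culture's class frequencies.

    Duplication-bearing classes are sampled binomially (integer founder
    cells per plate); the haploid bulk is taken in expectation.  The
    expected number of duplication-bearing cells per plate is
    ``duplication_frequency * n_plate``.
    """
    if n_plate < 1:
        raise ValueError("n_plate must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = culture.population.total()
    p = min(1.0, n_plate / total)
    classes: list[CellClass] = []
    for c in culture.population:
        if c.copy_number == 1:
            classes.append(CellClass(1, c.count * p))
        else:
            whole = int(c.count)
            frac = c.count - whole
            drawn = int(rng.binomial(whole, p)) if whole else 0
            if frac > 0 and rng.random() < frac * p:
                drawn += 1
            if drawn:
                classes.append(CellClass(c.copy_number, float(drawn), c.amplicon))
    return Population(classes)
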