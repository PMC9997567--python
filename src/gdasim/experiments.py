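"""In-silico experimental designs: fluctuation test, reconstruction,
replica plating, and the amplicon-size/appearance-day dataset.

Each harness composes the culture and plate simulators and emits the data
structure the corresponding statistical analysis consumes: a plate-by-day
count table (fluctuation), percent-visible curves for seeded mutant cells
(reconstruction), or same-position sibling-cluster counts (replica
plating).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RateConfig
from .core import AmpliconSpec, CellClass, Population, make_amplicon
from .nonselective import sample_plated_cells, simulate_culture
from .selection import simulate_plate

__all__ = [
    "PlateCountTable",
    "ReconstructionResult",
    "ReplicaPlatingResult",
    "run_fluctuation_experiment",
    "run_reconstruction",
    "run_replica_plating",
    "generate_amplicon_day_dataset",
]


@dataclass
class PlateCountTable:
    """Cumulative revertant colonies per plate per day.

    ``counts`` has one row per plate and one integer column per day
    (1-based).  ``culture_ids`` maps every plate to the culture it was
    poured from — the unit of a fluctuation analysis.
    """

    counts: pd.DataFrame
    culture_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.culture_ids) != self.counts.shape[0]:
            raise ValueError("one culture_id per plate required")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.shape[1] > 1 and (np.diff(values, axis=1) < 0).any():
            raise ValueError("cumulative counts must be non-decreasing over days")

    def day_counts(self, day: int) -> np.ndarray:
        return self.counts[day].to_numpy()

    @property
    def days(self) -> list[int]:
        return list(self.counts.columns)


def run_fluctuation_experiment(
    n_cultures: int,
    plates_per_culture: int,
    days: int,
    config: RateConfig,
    seed: int | None = None,
) -> PlateCountTable:
    """Grow independent cultures and plate aliquots on selective plates.

    The parallel-culture design uses ``plates_per_culture=1`` (fluctuation
    between cultures); the single-large-culture design uses
    ``n_cultures=1`` with many plates (within-culture, sampling-only
    variation).
    """
    if n_cultures < 1 or plates_per_culture < 1:
        raise ValueError("n_cultures and plates_per_culture must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    culture_ids = []
    for ci, child in enumerate(ss.spawn(n_cultures)):
        rng = np.random.default_rng(child)
        culture = simulate_culture(config.culture_final_size, config, rng)
        for _ in range(plates_per_culture):
            inoculum = sample_plated_cells(culture, config.n_plate, rng)
            timeline = simulate_plate(inoculum, days, config, rng)
            rows.append(timeline.visible_colonies)
            culture_ids.append(f"culture_{ci:03d}")
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        columns=list(range(1, days + 1)),
        index=[f"plate_{i:03d}" for i in range(len(rows))],
    )
    return PlateCountTable(
        counts=counts,
        culture_ids=culture_ids,
        metadata={
            "plates_per_culture": plates_per_culture,
            "config_hash": config.config_hash(),
            "seed": seed,
        },
    )


@dataclass
class ReconstructionResult:
    """Outcome of seeding known mutant cells into a dense parental lawn.

    ``percent_visible`` holds, per replicate plate and day, the percentage
    of the seeded cells that have formed visible colonies above the
    parent-only background (clamped to [0, 100] and non-decreasing).
    """

    percent_visible: pd.DataFrame  # plates x days
    background_counts: np.ndarray  # per-day counts of the parent-only plate
    n_seeded: int
    founder_copy_number: int

    def mean_percent(self) -> pd.Series:
        return self.percent_visible.mean(axis=0)

    def day_half_visible(self) -> float:
        """Median (across plates) of the first day >= 50% of seeded cells
        are visible.  Plates that never reach 50% within the horizon enter
        as +inf, so the median is infinite when most plates never crossed."""
        crossings = []
        for _, row in self.percent_visible.iterrows():
            above = row[row >= 50.0]
            crossings.append(float(above.index[0]) if len(above) else math.inf)
        return float(np.median(crossings))


def run_reconstruction(
    founder_copy_number: int,
    days: int,
    config: RateConfig,
    n_mutant_cells: int = 300,
    n_plates: int = 10,
    amplicon: AmpliconSpec | None = None,
    seed: int | None = None,
) -> ReconstructionResult:
    """Reconstruction experiment: seed ``n_mutant_cells`` cells of a known
    copy number (default: the 28 kb permissive amplicon) together with a
    full parental lawn, and follow the percent of seeded cells that have
    formed visible colonies above the parent-only background."""
    if founder_copy_number < 2:
        raise ValueError("founder copy number must be >= 2")
    if n_mutant_cells < 0:
        raise ValueError("n_mutant_cells must be >= 0")
    amp = amplicon or make_amplicon(28.0, permissive=True)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_plates + 2)

    # one parental culture feeds the whole trial (background included), as
    # in the bench protocol; plates differ only by sampling
    rng_culture = np.random.default_rng(children[-2])
    culture = simulate_culture(config.culture_final_size, config, rng_culture)

    rng_bg = np.random.default_rng(children[-1])
    inoculum = sample_plated_cells(culture, config.n_plate, rng_bg)
    background = simulate_plate(inoculum, days, config, rng_bg).visible_colonies

    percents = np.zeros((n_plates, days))
    for i in range(n_plates):
        rng = np.random.default_rng(children[i])
        inoculum = sample_plated_cells(culture, config.n_plate, rng)
        seeded = Population(
            inoculum.classes
            + ([CellClass(founder_copy_number, float(n_mutant_cells), amp)]
               if n_mutant_cells else [])
        )
        timeline = simulate_plate(seeded, days, config, rng)
        if n_mutant_cells:
            above = np.maximum(
                timeline.visible_colonies.astype(float) - background, 0.0
            )
            pct = np.clip(100.0 * above / n_mutant_cells, 0.0, 100.0)
        else:
            pct = np.zeros(days)
        percents[i] = np.maximum.accumulate(pct)

    return ReconstructionResult(
        percent_visible=pd.DataFrame(
            percents, columns=list(range(1, days + 1)),
            index=[f"plate_{i:02d}" for i in range(n_plates)],
        ),
        background_counts=background,
        n_seeded=n_mutant_cells,
        founder_copy_number=founder_copy_number,
    )


@dataclass
class ReplicaPlatingResult:
    n_master_colonies: int
    model: str
    singleton_revertants: tuple[int, int, int]  # per selective replica plate
    same_position_triples: int

    def __post_init__(self) -> None:
        if self.same_position_triples > self.n_master_colonies:
            raise ValueError("triples cannot exceed master colonies")


def _colony_precursor_counts(
    n_colonies: int, config: RateConfig, rng: np.random.Generator
) -> np.ndarray:
    """Permissive precursor cells per master microcolony.

    Each colony grows from one nonmutant cell for ~log2(master_colony_size)
    generations; duplication lineages arise along the way, so the
    per-colony precursor content is Luria-Delbrueck distributed: most
    colonies carry few or none, while a colony whose duplication arose
    early carries a large clonal precursor subpopulation (these are the
    colonies that print revertant clusters to every replica).  Collapse
    during nonselective growth (precursors are unstable without selection)
    and the permissive-endpoint requirement thin the counts.
    """
    gens = int(round(math.log2(config.master_colony_size)))
    decay = (1.0 - (config.k_rec + config.dup_cost_per_copy)) ** (gens / 2.0)
    wt = np.ones(n_colonies)
    mutants = np.zeros(n_colonies)
    rate = min(1.0, 2.0 * config.k_dup)  # per-division chance of a dup daughter
    for _ in range(gens):
        new = rng.binomial(np.maximum(wt, 0).astype(np.int64), rate)
        mutants = 2.0 * mutants + new
        wt = 2.0 * wt - new
    thinned = rng.binomial(
        mutants.astype(np.int64),
        min(1.0, decay * config.permissive_fraction),
    )
    return thinned


_VISIBILITY_CACHE: dict[tuple[str, int, int], float] = {}


def _visibility_probability(config: RateConfig, days: int, n_clones: int = 800) -> float:
    """Probability that one printed 2-copy precursor cell forms a visible
    colony within the observation window (cached Monte-Carlo estimate with
    a seed derived from the configuration, so repeated runs are
    deterministic and do not consume caller randomness)."""
    from .selection import simulate_clones

    key = (config.config_hash(), days, n_clones)
    if key not in _VISIBILITY_CACHE:
        amp = make_amplicon(28.0, permissive=True)
        rng = np.random.default_rng(
            int(config.config_hash(), 16) % 2**31 + days
        )
        appearance, _ = simulate_clones(2, amp, days, config, n_clones, rng)
        _VISIBILITY_CACHE[key] = float(np.mean(~np.isnan(appearance)))
    return _VISIBILITY_CACHE[key]


def run_replica_plating(
    n_master_colonies: int,
    model: str,
    days: int,
    config: RateConfig,
    seed: int | None = None,
    induction_rate: float | None = None,
) -> ReplicaPlatingResult:
    """Replica-print master colonies onto three selective plates.

    Printing transfers a diminishing fraction of each colony to each
    successive replica (``print_fraction``, halving per plate — prints get
    more diffuse).  Under ``"preexistence"`` the transferred precursor
    cells of a precursor-bearing colony seed revertant clusters at the
    same position on all three replicas (a same-position triple) whenever
    at least one transferred cell per plate reaches visibility within
    ``days``.  Under ``"induction"`` every plate position acquires a
    revertant independently at the pre-existence model's marginal
    per-plate rate (or an explicit ``induction_rate``), so triples occur
    only by positional coincidence (~rate cubed).
    """
    if n_master_colonies < 1:
        raise ValueError("n_master_colonies must be >= 1")
    if model not in ("preexistence", "induction"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    fractions = np.array([config.print_fraction * 0.5**i for i in range(3)])

    def preexistence_hits(generator: np.random.Generator) -> np.ndarray:
        n_prec = _colony_precursor_counts(n_master_colonies, config, generator)
        p_vis = _visibility_probability(config, days)
        transferred = generator.binomial(n_prec[:, None], fractions[None, :])
        visible = generator.binomial(transferred, p_vis)
        return visible > 0

    if model == "preexistence":
        hits = preexistence_hits(rng)
    else:
        if induction_rate is None:
            # matched marginals from an internal pre-existence draw
            reference = preexistence_hits(np.random.default_rng(rng.integers(2**31)))
            rates = reference.mean(axis=0)
        else:
            rates = np.full(3, induction_rate)
        hits = rng.random((n_master_colonies, 3)) < rates[None, :]

    triples = int(hits.all(axis=1).sum())
    per_plate = hits.sum(axis=0)
    singletons = tuple(int(per_plate[i] - triples) for i in range(3))
    return ReplicaPlatingResult(
        n_master_colonies=n_master_colonies,
        model=model,
        singleton_revertants=singletons,
        same_position_triples=triples,
    )


def generate_amplicon_day_dataset(
    n_revertants: int,
    config: RateConfig,
    seed: int | None = None,
    days: int = 30,
    max_plates: int = 20,
) -> pd.DataFrame:
    """Paired (appearance_day, amplicon length) records for rank-correlation
    analysis: the first ``n_revertants`` simulated colonies across as many
    reversion-assay plates as needed."""
    if n_revertants < 2:
        raise ValueError("n_revertants must be >= 2")
    ss = np.random.SeedSequence(seed)
    records: list[tuple[int, float]] = []
    for child in ss.spawn(max_plates):
        rng = np.random.default_rng(child)
        culture = simulate_culture(config.culture_final_size, config, rng)
        inoculum = sample_plated_cells(culture, config.n_plate, rng)
        timeline = simulate_plate(inoculum, days, config, rng)
        for rec in timeline.colony_records:
            records.append((rec.appearance_day, rec.amplicon.length_kb))
        if len(records) >= n_revertants:
            break
    if len(records) < n_revertants:
        raise RuntimeError(
            f"only {len(records)} colonies arose within {max_plates} plates; "
            "increase days or max_plates"
        )
    records.sort(key=lambda r: r[0])
    return pd.DataFrame(
        records[:n_revertants], columns=["appearance_day", "length_kb"]
    )
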