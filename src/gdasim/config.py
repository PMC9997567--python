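"""Model rates and plate parameters.

All tunable numbers of the duplication–amplification model live in a single
:class:`RateConfig`.  Rates are probabilities per cell per division unless
stated otherwise; plate quantities are cell counts.  The defaults encode the
study conditions of the Ben-reversion system: 5x10^8 parental cells per
selective plate, unequal-exchange probability ~1e-2 per repeat junction per
division, ~20 generations (1e6 cells) from a single founder to a visible
colony, and a selective growth law calibrated against the reconstruction
delays observed for 2-, 3-, 8- and 15-copy founders (see
``scripts/calibrate.py``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RateConfig"]

_PROBABILITY_FIELDS = (
    "k_dup",
    "k_rec",
    "intra_collapse_weight",
    "dup_cost_per_copy",
    "permissive_fraction",
)


@dataclass
class RateConfig:
    """All model rates and plate parameters.

    Parameters
    ----------
    k_dup
        Duplication-formation probability per (haploid) cell per division.
        Default 1e-6, chosen so that the analytic source/loss balance
        ``k_dup / k_rec`` reproduces the measured 0.01% duplication
        frequency in an unselected culture.
    k_rec
        Unequal-recombination probability per repeat junction per cell per
        division.  A cell with ``n`` tandem copies carries ``n - 1``
        junctions, so its per-division exchange probability is
        ``k_rec * (n - 1)`` (capped at 1).  Default 1e-2.
    intra_collapse_weight
        Intrachromosomal deletions between repeats collapse the array
        through the same junctions; each daughter cell of a division
        additionally jumps ``n -> n - d`` with probability
        ``intra_collapse_weight * k_rec * (n - 1)``.  The default 0.5
        brings the total per-division loss of the duplicated state to
        ~``k_rec``, matching the analytic source/loss balance.
    dup_cost_per_copy
        Relative nonselective fitness cost per extra amplicon copy,
        normalized to a 28 kb amplicon (see
        :func:`gdasim.core.nonselective_fitness`).  Default 0: the default
        steady state is the pure formation/collapse balance.
    g_max, k_half, hill
        Selective growth law ``g(n) = g_max * x**hill / (x**hill +
        k_half**hill)`` with ``x = n - 1`` divisions/day on benzoate plates;
        ``g(1) = 0`` (haploids cannot grow).  Values are calibrated against
        the reconstruction-delay targets; ``hill = 1`` recovers the simple
        saturating form ``g_max * (n-1) / (n-1 + k_half)``.
    n_vis
        Cells needed for a visible colony.  Default 1e6 (~20 generations
        from one cell).
    n_plate
        Parental cells spread per selective plate.  Default 5e8.
    permissive_fraction
        Fraction of duplications whose endpoints permit selectable
        amplification (one amplicon end is restricted to a ~5.5 kb region);
        only permissive precursors can grow under selection.  Calibrated
        against the day-19 revertant frequency (~1e-7).
    temp_factor
        Multiplier on plate event rates (growth and unequal exchange)
        representing 30C (1.0) versus 22C (~0.5) selective incubation.
    lawn_decline_fold
        Fold-decrease of the viable lawn over the first 12 days (default 10),
        with recovery to the starting size by day 21.
    plate_induction_rate
        Per-lawn-cell per-day duplication induction rate on the plate.
        Default 0 (the pre-existence model).  A nonzero value enables the
        explicit "adaptive" contrast model in which duplications are induced
        during selection.
    culture_final_size
        Saturation size of a simulated nonselective culture.  Default 5e8
        (one plate load; plating samples class frequencies).
    amplicon_min_kb, amplicon_max_kb
        Support of the amplicon length distribution (log-uniform), 12-290 kb.
    dt_days
        Sub-day time step for plate simulation (default 0.05 day).
    stochastic_threshold
        Cell-class counts below this value are advanced stochastically
        (integer sampling); larger classes deterministically in expectation.
    max_copy_number
        Cap on tracked tandem copy number (higher jumps are clipped).
    master_colony_size
        Cells per master-plate microcolony in replica-plating experiments.
    print_fraction
        Fraction of a master colony transferred to the first replica plate;
        halves for each successive print.
    seed
        Default RNG seed recorded in run manifests (functions accept an
        explicit seed as well).
    """

    # elementary event rates
    k_dup: float = 1e-6
    k_rec: float = 1e-2
    intra_collapse_weight: float = 0.5
    dup_cost_per_copy: float = 0.0
    ref_amplicon_kb: float = 28.0
    # selective growth law (calibrated; see scripts/calibrate.py)
    g_max: float = 16.0
    k_half: float = 25.0
    hill: float = 1.3
    # plate parameters
    n_vis: float = 1e6
    n_plate: float = 5e8
    permissive_fraction: float = 0.5
    temp_factor: float = 1.0
    lawn_decline_fold: float = 10.0
    plate_induction_rate: float = 0.0
    # nonselective culture
    culture_final_size: float = 5e8
    amplicon_min_kb: float = 12.0
    amplicon_max_kb: float = 290.0
    # numerics
    dt_days: float = 0.05
    stochastic_threshold: float = 1e4
    max_copy_number: int = 64
    # replica plating
    master_colony_size: float = 1e7
    print_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.k_half <= 0 or self.hill <= 0:
            raise ValueError("k_half and hill must be positive")
        if self.n_vis < 1:
            raise ValueError("n_vis must be >= 1")
        if self.n_plate < 1:
            raise ValueError("n_plate must be >= 1")
        if self.temp_factor <= 0:
            raise ValueError("temp_factor must be positive")
        if self.lawn_decline_fold < 1:
            raise ValueError("lawn_decline_fold must be >= 1")
        if not self.amplicon_min_kb <= self.amplicon_max_kb:
            raise ValueError("amplicon_min_kb must not exceed amplicon_max_kb")
        if self.dt_days <= 0 or self.dt_days > 1:
            raise ValueError("dt_days must lie in (0, 1]")
        if self.max_copy_number < 2:
            raise ValueError("max_copy_number must be >= 2")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RateConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RateConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RateConfig":
        """Load from YAML or JSON depending on suffix."""
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_yaml(path)

    def replace(self, **changes: Any) -> "RateConfig":
        return dataclasses.replace(self, **changes)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
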