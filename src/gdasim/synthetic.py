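"""Parametric plate-count generators and embedded fixtures.

These generators exist so the statistics suite can be exercised against
known distributional structure independently of the mechanistic simulator:
i.i.d. Poisson plate counts emulate within-culture (post-plating) noise,
while a deliberately simple Luria-Delbrueck lineage generator — doubling
population, binomial new mutants per generation, mutant lineages doubling
without loss — emulates between-culture jackpot structure.  The embedded
fixture reproduces the printed four-arm fluctuation-test distribution
(119 parallel cultures vs one 18-plate and two 49-plate single cultures,
day-10 counts).
"""

from __future__ import annotations

import numpy as np

__all__ = ["gen_poisson_plates", "gen_ld_plates", "table1_fixture"]


def gen_poisson_plates(
    lambda_: float, n_plates: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """i.i.d. Poisson revertant counts across plates (seed-deterministic)."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lambda_, size=n_plates).astype(np.int64)


def gen_ld_plates(
    mutation_rate: float,
    n_generations: int,
    n_final: float,
    n_cultures: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-culture mutant counts from a classic discrete-generation
    Luria-Delbrueck lineage simulation.

    Each culture grows from ``n_final / 2**n_generations`` cells; per
    generation the wild-type population doubles, new mutants arise
    binomially among the wild-type divisions, and existing mutant lineages
    double without loss.  This is intentionally simpler than the
    mechanistic duplication simulator — it generates the canonical jackpot
    distribution for testing statistics, not biology.
    """
    if mutation_rate < 0 or mutation_rate > 1:
        raise ValueError("mutation_rate must lie in [0, 1]")
    if n_generations < 1 or n_final < 1 or n_cultures < 1:
        raise ValueError("n_generations, n_final and n_cultures must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n0 = max(1.0, n_final / 2.0**n_generations)
    counts = np.zeros(n_cultures, dtype=np.int64)
    for i in range(n_cultures):
        wt = n0
        mutants = 0.0
        for _ in range(n_generations):
            new = rng.binomial(int(round(wt)), mutation_rate) if mutation_rate else 0
            mutants = 2.0 * mutants + new
            wt = 2.0 * wt - new
        counts[i] = int(round(mutants))
    return counts


# printed day-10 distributions: {count: number of plates}
_PARALLEL_ARM = {
    0: 48, 1: 24, 2: 21, 3: 7, 4: 8, 5: 1, 6: 1, 7: 1, 8: 1, 9: 1,
    10: 3, 12: 1, 17: 1, 19: 1,
}
_SINGLE_ARMS = (
    {0: 10, 1: 4, 2: 4},   # 18 plates from one large culture
    {0: 40, 1: 6, 2: 3},   # 49 plates
    {0: 39, 1: 9, 2: 1},   # 49 plates
)


def _expand(dist: dict[int, int]) -> np.ndarray:
    out: list[int] = []
    for value in sorted(dist):
        out.extend([value] * dist[value])
    return np.asarray(out, dtype=np.int64)


def table1_fixture() -> dict[str, np.ndarray]:
    """The embedded four-arm fluctuation-test distribution (day-10 counts).

    Returns fresh arrays keyed ``"parallel"`` (119 plates, one per
    independent culture) and ``"single_18"``, ``"single_49a"``,
    ``"single_49b"`` (plates of the three large single cultures).
    """
    return {
        "parallel": _expand(_PARALLEL_ARM),
        "single_18": _expand(_SINGLE_ARMS[0]),
        "single_49a": _expand(_SINGLE_ARMS[1]),
        "single_49b": _expand(_SINGLE_ARMS[2]),
    }
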