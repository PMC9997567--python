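"""In-silico NotI digestion band patterns for amplified chromosomes.

The wild-type chromosome digests into six NotI fragments (A 1,380; B 1,044;
C 622; D 259; E 197; F 97 kb); the cat gene cluster sits on the ~197 kb E
fragment.  A tandem amplification changes the pattern in one of two
diagnostic ways:

* amplicon confined within E (no internal NotI site): the E fragment is
  enlarged to ``E + (copies - 1) * length``; a mixed-copy-number population
  shows a ladder of enlarged E fragments with rungs one amplicon apart;
* amplicon spanning the E/D NotI site: each repeat is linearized by
  digestion, so E stays at 197 kb and a new band appears at the amplicon
  length with multiplicity ``copies - 1`` — its intensity reports the copy
  number.

Junction fragments at the array flanks are ignored (the ``copies - 1``
internal-repeat model); gel migration and detection thresholds are not
modelled — outputs are ideal size/intensity lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AmpliconSpec, Population

__all__ = ["WILD_TYPE_FRAGMENTS_KB", "BandPattern", "predict_noti_bands", "pattern_for_population"]

#: NotI fragments of the wild-type chromosome, largest to smallest.
WILD_TYPE_FRAGMENTS_KB: dict[str, float] = {
    "A": 1380.0,
    "B": 1044.0,
    "C": 622.0,
    "D": 259.0,
    "E": 197.0,
    "F": 97.0,
}

_E_KB = WILD_TYPE_FRAGMENTS_KB["E"]


@dataclass
class BandPattern:
    """Ideal digestion pattern: (size_kb, intensity) pairs, intensity in
    genome-equivalents (multiplicity for a single genome)."""

    bands: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for size, mult in self.bands:
            if size <= 0 or mult <= 0:
                raise ValueError("band sizes and intensities must be positive")
        self.bands = sorted(self.bands, key=lambda b: -b[0])

    def total_mass(self) -> float:
        return sum(size * mult for size, mult in self.bands)

    def sizes(self) -> list[float]:
        return [size for size, _ in self.bands]

    def merged(self, tol_kb: float = 1e-6) -> "BandPattern":
        out: list[tuple[float, float]] = []
        for size, mult in self.bands:
            if out and abs(out[-1][0] - size) <= tol_kb:
                out[-1] = (out[-1][0], out[-1][1] + mult)
            else:
                out.append((size, mult))
        return BandPattern(out)

    def scaled(self, factor: float) -> "BandPattern":
        return BandPattern([(s, m * factor) for s, m in self.bands])


def predict_noti_bands(amplicon: AmpliconSpec, copies: int) -> BandPattern:
    """NotI band pattern of a single genome with ``copies`` tandem copies."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    bands = [(size, 1.0) for name, size in WILD_TYPE_FRAGMENTS_KB.items() if name != "E"]
    if copies == 1:
        bands.append((_E_KB, 1.0))
    elif amplicon.spans_noti_site:
        # each repeat carries the E/D site and is linearized to amplicon length
        bands.append((_E_KB, 1.0))
        bands.append((amplicon.length_kb, float(copies - 1)))
    else:
        bands.append((_E_KB + (copies - 1) * amplicon.length_kb, 1.0))
    return BandPattern(bands).merged()


def pattern_for_population(population: Population) -> BandPattern:
    """Merged band pattern of a heterogeneous population.

    Intensities are per-class patterns weighted by class cell counts, so a
    mixture of copy numbers yields a ladder (confined amplicons) or a
    single amplicon-length band whose intensity grows with the mean copy
    number (spanning amplicons).
    """
    if not population.classes or population.total() <= 0:
        raise ValueError("population must be nonempty")
    bands: list[tuple[float, float]] = []
    for cls in population:
        if cls.count <= 0:
            continue
        amp = cls.amplicon if cls.copy_number >= 2 else None
        if amp is None:
            pattern = BandPattern(
                [(size, 1.0) for size in WILD_TYPE_FRAGMENTS_KB.values()]
            )
        else:
            pattern = predict_noti_bands(amp, cls.copy_number)
        bands.extend(pattern.scaled(cls.count).bands)
    return BandPattern(bands).merged()
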