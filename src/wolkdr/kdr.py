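"""Two-locus kdr genotypes, haplotype resolution and frequency estimation.

Diploid calls at NaV sites 1016 (Val/Ile) and 1534 (Phe/Cys) are resolved
into unordered pairs of the three haplotypes segregating in Brazilian
*Aedes aegypti*:

    ``S``  — 1016 Val + 1534 Phe (wild type)
    ``R1`` — 1016 Val + 1534 Cys (single mutant)
    ``R2`` — 1016 Ile + 1534 Cys (double mutant)

The fourth combination (1016 Ile + 1534 Phe) does not occur, which makes
phasing of any two-site genotype deterministic: at most one unordered pair
of permitted haplotypes pools to a given pair of site calls.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from ._stats import wilson_ci

logger = logging.getLogger(__name__)

__all__ = [
    "Haplotype",
    "KdrGenotype",
    "AlleleFrequencySet",
    "ImpossibleGenotypeError",
    "resolve_haplotypes",
    "allele_frequencies",
    "genotype_frequencies",
    "resistant_genotype_fraction",
    "RESISTANT_PAIRS",
]


class ImpossibleGenotypeError(ValueError):
    """Raised when a two-site genotype cannot be phased into permitted haplotypes."""


class Haplotype(enum.IntEnum):
    """The three permitted NaV haplotypes, ordered S < R1 < R2."""

    S = 0
    R1 = 1
    R2 = 2

    @property
    def site1016(self) -> str:
        return "I" if self is Haplotype.R2 else "V"

    @property
    def site1534(self) -> str:
        return "F" if self is Haplotype.S else "C"


#: canonical order for site calls so unordered pairs compare equal
_ORDER_1016 = {"V": 0, "I": 1}
_ORDER_1534 = {"F": 0, "C": 1}


def _normalize(pair: tuple[str, str], order: dict[str, int], site: str) -> tuple[str, str]:
    a, b = pair
    for call in (a, b):
        if call not in order:
            raise ValueError(f"invalid call {call!r} at site {site}")
    return tuple(sorted(pair, key=order.__getitem__))  # type: ignore[return-value]


@dataclass(frozen=True)
class KdrGenotype:
    """Unphased diploid calls at sites 1016 and 1534.

    Site calls are unordered pairs; ``("I", "V")`` normalizes to ``("V", "I")``.
    """

    site1016: tuple[str, str]
    site1534: tuple[str, str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "site1016", _normalize(self.site1016, _ORDER_1016, "1016"))
        object.__setattr__(self, "site1534", _normalize(self.site1534, _ORDER_1534, "1534"))


# exhaustive pooled-call -> haplotype-pair table over the 6 unordered pairs
_POOL_TABLE: dict[tuple[tuple[str, str], tuple[str, str]], tuple[Haplotype, Haplotype]] = {}
for _pair in combinations_with_replacement(Haplotype, 2):
    _key = (
        _normalize((_pair[0].site1016, _pair[1].site1016), _ORDER_1016, "1016"),
        _normalize((_pair[0].site1534, _pair[1].site1534), _ORDER_1534, "1534"),
    )
    assert _key not in _POOL_TABLE  # uniqueness is what makes phasing deterministic
    _POOL_TABLE[_key] = _pair


def resolve_haplotypes(g: KdrGenotype) -> tuple[Haplotype, Haplotype]:
    """Phase a two-site genotype into its unique unordered haplotype pair.

    Raises
    ------
    ImpossibleGenotypeError
        If no pair of permitted haplotypes pools to the observed calls
        (any genotype requiring the forbidden Ile+Phe haplotype).
    """
    try:
        return _POOL_TABLE[(g.site1016, g.site1534)]
    except KeyError:
        raise ImpossibleGenotypeError(
            f"impossible genotype for sample {g.sample_id or '<unnamed>'}: "
            f"1016 {g.site1016[0]}/{g.site1016[1]}, 1534 {g.site1534[0]}/{g.site1534[1]} "
            "(requires the forbidden Ile+Phe haplotype)"
        ) from None


def pair_name(pair: tuple[Haplotype, Haplotype]) -> str:
    a, b = sorted(pair)
    return f"{a.name}{b.name}" if a != Haplotype.S else ("SS" if b == Haplotype.S else f"S{b.name}")


#: the six unordered genotype classes, in deterministic S < R1 < R2 order
GENOTYPE_CLASSES = tuple(
    pair_name(p) for p in combinations_with_replacement(Haplotype, 2)
)
RESISTANT_PAIRS = ("R1R1", "R1R2", "R2R2")


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Per-haplotype allele frequencies with Wilson confidence intervals."""

    frequencies: dict[str, float]
    n_alleles: int
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if self.n_alleles % 2 != 0:
            raise ValueError("n_alleles must be even (diploid samples)")


def allele_frequencies(
    genos: list[KdrGenotype], ci_level: float = 0.95
) -> AlleleFrequencySet:
    """Haplotype (allele) frequencies over 2N chromosomes with Wilson CIs."""
    if not genos:
        raise ValueError("no genotypes supplied")
    counts: Counter[Haplotype] = Counter()
    for g in genos:
        counts.update(resolve_haplotypes(g))
    n_alleles = 2 * len(genos)
    freqs = {h.name: counts.get(h, 0) / n_alleles for h in Haplotype}
    ci_low, ci_high = {}, {}
    for h in Haplotype:
        lo, hi = wilson_ci(counts.get(h, 0), n_alleles, ci_level)
        ci_low[h.name], ci_high[h.name] = lo, hi
    return AlleleFrequencySet(freqs, n_alleles, ci_low, ci_high, ci_level)


def genotype_frequencies(genos: list[KdrGenotype]) -> dict[str, float]:
    """Proportions of the six unordered haplotype-pair classes, summing to 1."""
    if not genos:
        raise ValueError("no genotypes supplied")
    counts: Counter[str] = Counter(pair_name(resolve_haplotypes(g)) for g in genos)
    n = len(genos)
    return {name: counts.get(name, 0) / n for name in GENOTYPE_CLASSES}


def resistant_genotype_fraction(freqs: dict[str, float]) -> float:
    """Summed frequency of the fully resistant classes R1R1, R1R2 and R2R2."""
    total = sum(freqs.values())
    if freqs and abs(total - 1.0) > 1e-9:
        raise ValueError(f"genotype frequencies sum to {total}, not 1")
    return sum(freqs.get(name, 0.0) for name in RESISTANT_PAIRS)
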