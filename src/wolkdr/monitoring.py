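"""Wolbachia infection-frequency monitoring and maternal-transmission estimators.

Covers four field/lab screens used when tracking an endosymbiont release:
weekly trap positivity, mtDNA-marker leakage in field catches, per-dam
larval transmission fidelity, and the colony quality-assurance threshold.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._stats import wilson_ci

logger = logging.getLogger(__name__)

__all__ = [
    "TrapWeekRecord",
    "MtdnaScreen",
    "DamRecord",
    "TransmissionScreen",
    "FidelityResult",
    "QAResult",
    "frequency_series",
    "leakage_rate",
    "transmission_fidelity",
    "uninfected_share_of_top_dam",
    "colony_qa",
]


@dataclass(frozen=True)
class TrapWeekRecord:
    """One week of trap screening: mosquitoes tested and Wolbachia-positive."""

    week: int
    n_tested: int
    n_positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_tested:
            raise ValueError(
                f"week {self.week}: n_positive {self.n_positive} outside [0, {self.n_tested}]"
            )


@dataclass(frozen=True)
class MtdnaScreen:
    """Field catch screened for the release-strain COI SNP and infection status.

    ``n_marked`` individuals carry the release-strain mitochondrial marker;
    ``n_marked_negative`` of those test Wolbachia-negative (transmission
    leakage in the marked maternal lineage).
    """

    n_tested: int
    n_marked: int
    n_marked_negative: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_marked <= self.n_tested:
            raise ValueError("n_marked outside [0, n_tested]")
        if not 0 <= self.n_marked_negative <= self.n_marked:
            raise ValueError("n_marked_negative outside [0, n_marked]")


@dataclass(frozen=True)
class DamRecord:
    dam_id: str
    dam_infected: bool
    larvae_infected: int
    larvae_uninfected: int

    def __post_init__(self) -> None:
        if self.larvae_infected < 0 or self.larvae_uninfected < 0:
            raise ValueError(f"dam {self.dam_id}: negative larval counts")

    @property
    def larvae_total(self) -> int:
        return self.larvae_infected + self.larvae_uninfected


@dataclass(frozen=True)
class TransmissionScreen:
    """Per-dam infection status with counts of screened infected/uninfected larvae."""

    dams: tuple[DamRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dams", tuple(self.dams))
        dup = [d for d, k in Counter(x.dam_id for x in self.dams).items() if k > 1]
        if dup:
            raise ValueError(f"duplicate dam ids: {sorted(dup)}")


@dataclass(frozen=True)
class FidelityResult:
    dam_rate: float
    larval_rate: float
    n_dams: int
    n_dams_infected: int
    n_larvae: int
    n_larvae_infected: int
    excluded_uninfected_dams: bool


@dataclass(frozen=True)
class QAResult:
    passed: bool
    frequency: float
    threshold: float
    n_positive: int
    n_tested: int


def frequency_series(
    records: list[TrapWeekRecord], ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-week infection frequency with Wilson CIs.

    Weeks with no catches are emitted with NaN frequency rather than 0:
    absence of data is not absence of infection.

    Raises
    ------
    ValueError
        On duplicate week indices (listing the offending weeks).
    """
    dup = [w for w, k in Counter(r.week for r in records).items() if k > 1]
    if dup:
        raise ValueError(f"duplicate weeks in trap series: {sorted(dup)}")
    rows = []
    for r in sorted(records, key=lambda r: r.week):
        if r.n_tested == 0:
            rows.append((r.week, 0, 0, math.nan, math.nan, math.nan))
            continue
        lo, hi = wilson_ci(r.n_positive, r.n_tested, ci_level)
        rows.append((r.week, r.n_tested, r.n_positive, r.n_positive / r.n_tested, lo, hi))
    return pd.DataFrame(
        rows, columns=["week", "n_tested", "n_positive", "frequency", "ci_low", "ci_high"]
    )


def leakage_rate(
    screen: MtdnaScreen, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Maternal-transmission leakage among marker-carrying individuals.

    Rate is ``n_marked_negative / n_marked`` with a Wilson interval.
    """
    if screen.n_marked == 0:
        raise ValueError("no marked individuals in screen")
    rate = screen.n_marked_negative / screen.n_marked
    return rate, wilson_ci(screen.n_marked_negative, screen.n_marked, ci_level)


def transmission_fidelity(
    screen: TransmissionScreen, exclude_uninfected_dams: bool = False
) -> FidelityResult:
    """Dam-level and larva-level Wolbachia transmission rates.

    With ``exclude_uninfected_dams`` the larvae of Wolbachia-negative dams
    are removed from both numerator and denominator of the larval rate
    (their lineages cannot transmit maternally); the dam rate is always
    computed over all dams.
    """
    if not screen.dams or all(d.larvae_total == 0 for d in screen.dams):
        raise ValueError("screen has no dams with larvae")
    n_dams = len(screen.dams)
    n_dams_infected = sum(d.dam_infected for d in screen.dams)
    pool = screen.dams
    if exclude_uninfected_dams:
        excluded = [d for d in pool if not d.dam_infected]
        for d in excluded:
            logger.info(
                "excluding uninfected dam %s (%d larvae) from larval rate",
                d.dam_id, d.larvae_total,
            )
        pool = tuple(d for d in pool if d.dam_infected)
    n_larvae = sum(d.larvae_total for d in pool)
    if n_larvae == 0:
        raise ValueError("no larvae remain after excluding uninfected dams")
    n_larvae_infected = sum(d.larvae_infected for d in pool)
    return FidelityResult(
        dam_rate=n_dams_infected / n_dams,
        larval_rate=n_larvae_infected / n_larvae,
        n_dams=n_dams,
        n_dams_infected=n_dams_infected,
        n_larvae=n_larvae,
        n_larvae_infected=n_larvae_infected,
        excluded_uninfected_dams=exclude_uninfected_dams,
    )


def uninfected_share_of_top_dam(screen: TransmissionScreen) -> float:
    """Largest single-dam share of all uninfected larvae in the screen."""
    total_uninfected = sum(d.larvae_uninfected for d in screen.dams)
    if total_uninfected == 0:
        raise ValueError("screen has no uninfected larvae")
    return max(d.larvae_uninfected for d in screen.dams) / total_uninfected


def colony_qa(n_positive: int, n_tested: int, threshold: float = 0.98) -> QAResult:
    """Check colony infection frequency against the release-support threshold."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_positive <= n_tested:
        raise ValueError("n_positive outside [0, n_tested]")
    freq = n_positive / n_tested
    return QAResult(freq >= threshold, freq, threshold, n_positive, n_tested)
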