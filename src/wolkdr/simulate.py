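"""Synthetic-data generators for every input the pipeline consumes.

Each generator draws from the statistical model its downstream estimator
assumes, so round-trip tests (generate -> estimate -> compare to truth) are
meaningful: kdr cohorts are Hardy-Weinberg draws from three-haplotype
frequencies, trap series are binomial draws from a frequency trajectory,
transmission screens apply an independent per-larva leakage rate, and
bioassay kills are binomial draws from a probit dose-response curve.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .bioassay import DoseRecord, DoseResponseTable
from .kdr import Haplotype, KdrGenotype
from .monitoring import DamRecord, TransmissionScreen, TrapWeekRecord

__all__ = [
    "SyntheticConfig",
    "default_scenario",
    "logistic_trajectory",
    "gen_kdr_cohort",
    "gen_trap_series",
    "gen_transmission_screen",
    "gen_bioassay",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario for one full synthetic run (paper-scale defaults)."""

    seed: int = 0
    # kdr cohort
    kdr_cohort_size: int = 500
    kdr_freqs: tuple[float, float, float] = (0.02, 0.35, 0.63)  # (fS, fR1, fR2)
    # trap series: logistic rise over the release period
    n_weeks: int = 20
    weekly_n_tested: int = 60
    trajectory_peak: float = 0.65
    trajectory_midweek: float = 10.0
    trajectory_rate: float = 0.4
    # transmission screen
    n_dams: int = 249
    dam_infection_rate: float = 0.996
    leakage: float = 0.024
    larvae_per_dam: int = 20
    # bioassay probit parameters per population: {name: (a, b)}
    probit_params: dict = field(
        default_factory=lambda: {"reference": (0.0, 2.0), "field": (-1.2, 2.0)}
    )
    bioassay_doses: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
    bioassay_n_per_dose: int = 100
    # fitness-cost stage configuration (passed through to MonteCarloConfig)
    fitness_cost: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.kdr_freqs) - 1.0) > 1e-9:
            raise ValueError("kdr haplotype frequencies must sum to 1")
        if not 0.0 <= self.leakage <= 1.0:
            raise ValueError("leakage outside [0, 1]")
        if self.larvae_per_dam > 20:
            raise ValueError("larvae_per_dam capped at 20 (sub-sample design)")

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("kdr_freqs", "bioassay_doses"):
            if key in d:
                d[key] = tuple(d[key])
        if "probit_params" in d:
            d["probit_params"] = {k: tuple(v) for k, v in d["probit_params"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kdr_freqs"] = list(self.kdr_freqs)
        d["bioassay_doses"] = list(self.bioassay_doses)
        d["probit_params"] = {k: list(v) for k, v in self.probit_params.items()}
        return d


def default_scenario(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


def logistic_trajectory(
    week: float, peak: float = 0.65, midweek: float = 10.0, rate: float = 0.4
) -> float:
    """Logistic infection-frequency curve rising toward ``peak``."""
    return peak / (1.0 + math.exp(-rate * (week - midweek)))


def gen_kdr_cohort(
    n: int,
    freqs: tuple[float, float, float],
    rng: np.random.Generator,
    prefix: str = "M",
) -> list[KdrGenotype]:
    """Draw diploid genotypes at Hardy-Weinberg from (fS, fR1, fR2).

    Two haplotypes per individual are drawn i.i.d. and pooled into site
    calls, so the forbidden Ile+Phe combination can never arise.
    """
    if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must be a probability vector")
    haps = rng.choice(3, size=(n, 2), p=list(freqs))
    cohort = []
    for i, (h1, h2) in enumerate(haps):
        a, b = Haplotype(h1), Haplotype(h2)
        cohort.append(
            KdrGenotype(
                (a.site1016, b.site1016), (a.site1534, b.site1534),
                sample_id=f"{prefix}{i:04d}",
            )
        )
    return cohort


def gen_trap_series(
    trajectory: list[float] | tuple[float, ...],
    n_tested: int,
    rng: np.random.Generator,
) -> list[TrapWeekRecord]:
    """Binomial weekly positives from a true frequency trajectory."""
    records = []
    for week, p in enumerate(trajectory, start=1):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"week {week}: trajectory value {p} outside [0, 1]")
        records.append(TrapWeekRecord(week, n_tested, int(rng.binomial(n_tested, p))))
    return records


def gen_transmission_screen(
    n_dams: int,
    dam_infection_rate: float,
    leakage: float,
    larvae_per_dam: int,
    rng: np.random.Generator,
) -> TransmissionScreen:
    """Per-dam screens: infected dams leak each larva independently at ``leakage``;
    uninfected dams produce only uninfected larvae."""
    dams = []
    for i in range(n_dams):
        infected = bool(rng.random() < dam_infection_rate)
        n_larvae = larvae_per_dam
        if infected:
            n_uninf = int(rng.binomial(n_larvae, leakage))
        else:
            n_uninf = n_larvae
        dams.append(
            DamRecord(
                dam_id=f"D{i:04d}",
                dam_infected=infected,
                larvae_infected=n_larvae - n_uninf,
                larvae_uninfected=n_uninf,
            )
        )
    return TransmissionScreen(tuple(dams))


def gen_bioassay(
    population: str,
    compound: str,
    doses: tuple[float, ...],
    n_per_dose: int,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> DoseResponseTable:
    """Binomial kills from mortality Phi(a + b*log10(dose))."""
    if b <= 0:
        raise ValueError("probit slope b must be positive")
    records = []
    for dose in doses:
        if dose <= 0:
            raise ValueError("doses must be positive")
        p = float(norm.cdf(a + b * math.log10(dose)))
        records.append(DoseRecord(dose, n_per_dose, int(rng.binomial(n_per_dose, p))))
    return DoseResponseTable(population, compound, tuple(records))
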