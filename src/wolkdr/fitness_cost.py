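"""Two-allele colony selection model and rejection-sampling cost inference.

The model tracks genotype frequencies (RR, RS, SS) of a resistance allele R
in a closed laboratory colony across discrete, non-overlapping generations.
Each generation applies viability/fitness weighting

    w_RR = 1 - c,   w_RS = 1 - d*c,   w_SS = 1

followed by random union of gametes. At scheduled generations, field-caught
resistant males are introgressed into the male mating pool at a fixed
male:female ratio. The homozygous cost ``c`` is inferred by rejection
sampling: draw ``c`` and the initial RR frequency from priors, simulate the
colony forward, and accept draws whose final R-allele frequency falls
within a tolerance window around the observed terminal frequency. Accepted
draws approximate the posterior of ``c``.

Two introgression semantics are provided (``migrants_selected``):

* ``True`` (default) — added males join the named generation's male pool
  and their gametes are weighted by the same genotype fitnesses as colony
  males (the cost includes adult components such as mating competitiveness
  and longevity, which field-reared adults also pay).
* ``False`` — added males are appended to the post-selection male gamete
  pool unweighted (pure allele-frequency migration).

The default reading reproduces the published posterior regime; the
alternative yields a noticeably heavier posterior (documented in the test
suite) because unweighted resistant migrants require a larger ``c`` to
purge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "GenotypeState",
    "IntrogressionEvent",
    "MonteCarloConfig",
    "CostPosterior",
    "ExtinctionError",
    "sample_initial_state",
    "gamete_frequency",
    "introgress_males",
    "next_generation",
    "simulate_trajectory",
    "run_rejection",
    "summarize_posterior",
]


class ExtinctionError(ValueError):
    """Mean fitness is zero: the modelled population is extinct."""


@dataclass(frozen=True)
class SelectionParams:
    """Homozygote cost ``c`` and heterozygote cost multiplier ``d``."""

    c: float
    d: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"cost c={self.c} outside [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"multiplier d={self.d} outside [0, 1]")

    @property
    def fitnesses(self) -> tuple[float, float, float]:
        """(w_RR, w_RS, w_SS)."""
        return 1.0 - self.c, 1.0 - self.d * self.c, 1.0


@dataclass(frozen=True)
class GenotypeState:
    """Genotype frequencies of one colony generation (F-label in ``generation``)."""

    f_RR: float
    f_RS: float
    f_SS: float
    generation: int = 1

    def __post_init__(self) -> None:
        for name, f in (("f_RR", self.f_RR), ("f_RS", self.f_RS), ("f_SS", self.f_SS)):
            if f < -1e-12:
                raise ValueError(f"{name}={f} is negative")
        total = self.f_RR + self.f_RS + self.f_SS
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")

    @property
    def allele_freq(self) -> float:
        """Frequency of the R allele."""
        return self.f_RR + 0.5 * self.f_RS


@dataclass(frozen=True)
class IntrogressionEvent:
    """Addition of donor males to the colony's male pool at one generation.

    ``male_ratio`` is added males per colony female (a 1:1 colony sex ratio
    is assumed, so the migrant fraction among males is ratio/(1+ratio)).
    Donor males are drawn from Hardy-Weinberg proportions at
    ``donor_allele_freq`` (1.0 = resistant homozygotes).
    """

    generation: int
    male_ratio: float = 0.1
    donor_allele_freq: float = 1.0

    def __post_init__(self) -> None:
        if self.male_ratio < 0:
            raise ValueError("male_ratio must be >= 0")
        if not 0.0 <= self.donor_allele_freq <= 1.0:
            raise ValueError("donor_allele_freq outside [0, 1]")


DEFAULT_EVENTS = (IntrogressionEvent(10), IntrogressionEvent(15))


@dataclass(frozen=True)
class MonteCarloConfig:
    """Full configuration of one rejection-sampling run."""

    n_draws: int = 100_000
    f_RR_prior: tuple[float, float] = (0.50, 0.60)
    initial_allele_freq: float = 0.60
    cost_prior: tuple[float, float] = (0.0, 1.0)
    het_cost_multiplier: float = 0.9
    target_freq: float = 0.03
    tolerance: float = 0.01
    events: tuple[IntrogressionEvent, ...] = DEFAULT_EVENTS
    n_generations: int = 17
    seed: int = 0
    drift_popsize: int | None = None
    migrants_selected: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        for name, (lo, hi) in (("f_RR_prior", self.f_RR_prior), ("cost_prior", self.cost_prior)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} {lo, hi} not an interval within [0, 1]")
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def from_dict(cls, d: dict) -> "MonteCarloConfig":
        d = dict(d)
        if "events" in d:
            d["events"] = tuple(
                IntrogressionEvent(**e) if isinstance(e, dict) else e for e in d["events"]
            )
        for key in ("f_RR_prior", "cost_prior"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "MonteCarloConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CostPosterior:
    """Accepted cost draws with summary statistics."""

    accepted_costs: np.ndarray
    accepted_f_RR: np.ndarray
    n_draws: int
    seed: int

    @property
    def n_accepted(self) -> int:
        return int(self.accepted_costs.size)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_draws

    @property
    def mean_cost(self) -> float:
        return float(np.mean(self.accepted_costs))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accepted_costs, [2.5, 97.5])
        return float(lo), float(hi)


def sample_initial_state(u1: float, config: MonteCarloConfig) -> GenotypeState:
    """Map a uniform deviate to the F1 genotype state.

    ``f_RR`` is uniform on the prior interval; heterozygotes are set so the
    R-allele frequency equals ``initial_allele_freq`` exactly.
    """
    lo, hi = config.f_RR_prior
    f_RR = lo + u1 * (hi - lo)
    f_RS = 2.0 * (config.initial_allele_freq - f_RR)
    f_SS = 1.0 - f_RR - f_RS
    if f_RS < 0 or f_SS < 0:
        raise ValueError(
            f"f_RR={f_RR} incompatible with allele frequency {config.initial_allele_freq}"
        )
    return GenotypeState(f_RR, f_RS, f_SS, generation=1)


def gamete_frequency(state: GenotypeState, params: SelectionParams) -> float:
    """Post-selection R-allele frequency among gametes."""
    w_RR, w_RS, _ = params.fitnesses
    mean_w = state.f_RR * w_RR + state.f_RS * w_RS + state.f_SS
    if mean_w <= 0.0:
        raise ExtinctionError("population extinct: mean fitness is zero")
    return (state.f_RR * w_RR + 0.5 * state.f_RS * w_RS) / mean_w


def introgress_males(p_male: float, event: IntrogressionEvent) -> float:
    """Allele-frequency migration of donor males into the male gamete pool."""
    r = event.male_ratio
    return (p_male + r * event.donor_allele_freq) / (1.0 + r)


def next_generation(p_female: float, p_male: float, generation: int = 0) -> GenotypeState:
    """Offspring genotype frequencies from random union of gametes."""
    f_RR = p_female * p_male
    f_RS = p_female * (1.0 - p_male) + (1.0 - p_female) * p_male
    f_SS = (1.0 - p_female) * (1.0 - p_male)
    return GenotypeState(f_RR, f_RS, f_SS, generation=generation)


def _mix_male_pool(state: GenotypeState, event: IntrogressionEvent) -> GenotypeState:
    """Male genotype pool after adding donor males (HWE at donor frequency)."""
    w = event.male_ratio / (1.0 + event.male_ratio)
    pd = event.donor_allele_freq
    donor = (pd * pd, 2.0 * pd * (1.0 - pd), (1.0 - pd) ** 2)
    return GenotypeState(
        (1.0 - w) * state.f_RR + w * donor[0],
        (1.0 - w) * state.f_RS + w * donor[1],
        (1.0 - w) * state.f_SS + w * donor[2],
        generation=state.generation,
    )


def simulate_trajectory(
    init: GenotypeState,
    params: SelectionParams,
    events: Sequence[IntrogressionEvent] = (),
    n_generations: int = 17,
    drift_popsize: int | None = None,
    rng: np.random.Generator | None = None,
    migrants_selected: bool = True,
) -> list[GenotypeState]:
    """Iterate the selection/introgression recursion for ``n_generations`` steps.

    Returns ``n_generations + 1`` states, the first being ``init``. The
    event whose ``generation`` equals a state's label perturbs the male
    pool of that generation and therefore shapes the next one's offspring.
    With ``drift_popsize`` set, offspring genotype counts are resampled
    multinomially at that census size.
    """
    events_by_gen: dict[int, IntrogressionEvent] = {}
    for e in events:
        if e.generation in events_by_gen:
            raise ValueError(f"multiple introgression events at generation {e.generation}")
        events_by_gen[e.generation] = e
    if drift_popsize is not None and rng is None:
        raise ValueError("drift_popsize requires an rng")

    states = [init]
    state = init
    for _ in range(n_generations):
        event = events_by_gen.get(state.generation)
        p_f = gamete_frequency(state, params)
        if event is None:
            p_m = p_f
        elif migrants_selected:
            p_m = gamete_frequency(_mix_male_pool(state, event), params)
        else:
            p_m = introgress_males(p_f, event)
        nxt = next_generation(p_f, p_m, generation=state.generation + 1)
        if drift_popsize is not None:
            counts = rng.multinomial(drift_popsize, (nxt.f_RR, nxt.f_RS, nxt.f_SS))
            nxt = GenotypeState(*(counts / drift_popsize), generation=nxt.generation)
        states.append(nxt)
        state = nxt
    return states


def _final_allele_freq_vec(
    c: np.ndarray, f_RR0: np.ndarray, config: MonteCarloConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized terminal R-allele frequency for arrays of prior draws.

    Mirrors :func:`simulate_trajectory` exactly (tested for agreement);
    kept separate so a 1e5-draw rejection run stays in the seconds range.
    """
    d = config.het_cost_multiplier
    p0 = config.initial_allele_freq
    f_RR = np.asarray(f_RR0, dtype=float).copy()
    f_RS = 2.0 * (p0 - f_RR)
    f_SS = 1.0 - f_RR - f_RS
    if np.any(f_RS < 0) or np.any(f_SS < 0):
        raise ValueError("initial state outside the simplex")
    w_RR = 1.0 - c
    w_RS = 1.0 - d * c
    events_by_gen = {e.generation: e for e in config.events}

    def gametes(g_RR, g_RS, g_SS):
        mean_w = g_RR * w_RR + g_RS * w_RS + g_SS
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean_w > 0, (g_RR * w_RR + 0.5 * g_RS * w_RS) / mean_w, np.nan)

    for gen in range(1, config.n_generations + 1):
        p_f = gametes(f_RR, f_RS, f_SS)
        event = events_by_gen.get(gen)
        if event is None:
            p_m = p_f
        elif config.migrants_selected:
            w = event.male_ratio / (1.0 + event.male_ratio)
            pd_ = event.donor_allele_freq
            donor = (pd_ * pd_, 2.0 * pd_ * (1.0 - pd_), (1.0 - pd_) ** 2)
            p_m = gametes(
                (1.0 - w) * f_RR + w * donor[0],
                (1.0 - w) * f_RS + w * donor[1],
                (1.0 - w) * f_SS + w * donor[2],
            )
        else:
            p_m = (p_f + event.male_ratio * event.donor_allele_freq) / (1.0 + event.male_ratio)
        f_RR = p_f * p_m
        f_RS = p_f * (1.0 - p_m) + (1.0 - p_f) * p_m
        f_SS = (1.0 - p_f) * (1.0 - p_m)
        if config.drift_popsize is not None:
            n = config.drift_popsize
            probs = np.clip(np.stack([f_RR, f_RS, f_SS], axis=-1), 0.0, 1.0)
            probs /= probs.sum(axis=-1, keepdims=True)
            counts = rng.multinomial(n, probs)
            f_RR, f_RS, f_SS = (counts / n)[..., 0], (counts / n)[..., 1], (counts / n)[..., 2]
    return f_RR + 0.5 * f_RS


def run_rejection(config: MonteCarloConfig) -> CostPosterior:
    """Rejection-sample the posterior of the homozygous fitness cost.

    For each of ``n_draws`` replicates, draw the cost then the initial RR
    frequency from their uniform priors (all costs drawn first, then all
    initial frequencies, from one seeded generator — bit-reproducible),
    simulate the colony, and accept draws whose terminal R-allele frequency
    lies in ``[target - tolerance, target + tolerance]`` (inclusive).
    """
    rng = np.random.default_rng(config.seed)
    c = rng.uniform(*config.cost_prior, config.n_draws)
    f_RR0 = rng.uniform(*config.f_RR_prior, config.n_draws)
    logger.info("rejection run: %d draws, seed %d", config.n_draws, config.seed)

    chunk = 10_000
    finals = np.empty(config.n_draws)
    for start in range(0, config.n_draws, chunk):
        stop = min(start + chunk, config.n_draws)
        finals[start:stop] = _final_allele_freq_vec(c[start:stop], f_RR0[start:stop], config, rng)
        logger.info("simulated %d / %d draws", stop, config.n_draws)

    lo = config.target_freq - config.tolerance
    hi = config.target_freq + config.tolerance
    with np.errstate(invalid="ignore"):
        accepted = (finals >= lo) & (finals <= hi)
    n_acc = int(accepted.sum())
    logger.info("accepted %d draws (rate %.4f)", n_acc, n_acc / config.n_draws)
    if n_acc == 0:
        raise ValueError(
            "rejection sampler accepted no draws; review the cost prior, the "
            "target frequency and the tolerance window"
        )
    return CostPosterior(
        accepted_costs=c[accepted],
        accepted_f_RR=f_RR0[accepted],
        n_draws=config.n_draws,
        seed=config.seed,
    )


def summarize_posterior(p: CostPosterior, n_bins: int = 20) -> dict:
    """Summary report: mean, equal-tailed 95% CI, acceptance, histogram."""
    if p.n_accepted == 0:
        raise ValueError("empty posterior")
    ci_low, ci_high = p.ci
    counts, edges = np.histogram(p.accepted_costs, bins=n_bins)
    return {
        "mean_cost": p.mean_cost,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n_accepted": p.n_accepted,
        "n_draws": p.n_draws,
        "acceptance_rate": p.acceptance_rate,
        "seed": p.seed,
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }
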