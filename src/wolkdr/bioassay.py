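"""Probit dose-response fitting and resistance ratios.

Mortality is modelled as probit(p) = a + b*log10(dose) and fitted by
maximum likelihood (binomial GLM, probit link). Lethal concentrations are
read off the fitted line, LCq = 10**((probit(q) - a) / b), and resistance
ratios divide a test population's LC by the susceptible reference strain's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DoseRecord",
    "DoseResponseTable",
    "ProbitFit",
    "ResistanceRatio",
    "ProbitFitError",
    "fit_probit",
    "resistance_ratio",
    "compute_resistance_ratios",
    "kdt_ratio",
    "classify_resistance",
]


class ProbitFitError(ValueError):
    """Raised when a dose-response table cannot support a probit fit."""


@dataclass(frozen=True)
class DoseRecord:
    dose: float
    n_exposed: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"negative dose {self.dose}")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError(f"dose {self.dose}: n_dead outside [0, n_exposed]")


@dataclass(frozen=True)
class DoseResponseTable:
    population: str
    compound: str
    records: tuple[DoseRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))


@dataclass(frozen=True)
class ProbitFit:
    """ML probit fit on the log10(dose) scale."""

    intercept: float
    slope: float
    slope_se: float
    lc50: float
    lc90: float
    lc95: float
    converged: bool
    control_mortality: float = 0.0
    heterogeneity: float | None = None  # Pearson chi2 / df

    def lc(self, q: float) -> float:
        """Concentration killing a fraction ``q`` of exposed individuals."""
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")
        return float(10.0 ** ((norm.ppf(q) - self.intercept) / self.slope))


@dataclass(frozen=True)
class ResistanceRatio:
    rr50: float
    rr90: float
    rr95: float
    classification: str


def fit_probit(table: DoseResponseTable) -> ProbitFit:
    """Maximum-likelihood probit fit of mortality on log10(dose).

    Zero-dose records, when present, estimate control mortality and trigger
    Abbott's correction of the treated proportions; they are excluded from
    the regression itself.
    """
    controls = [r for r in table.records if r.dose == 0]
    treated = [r for r in table.records if r.dose > 0 and r.n_exposed > 0]
    doses = sorted({r.dose for r in treated})
    if len(doses) < 3:
        raise ProbitFitError(
            f"{table.population}/{table.compound}: need >= 3 distinct positive doses, "
            f"got {len(doses)}"
        )

    p0 = 0.0
    if controls:
        n_ctrl = sum(r.n_exposed for r in controls)
        p0 = sum(r.n_dead for r in controls) / n_ctrl if n_ctrl else 0.0
        if p0 >= 1.0:
            raise ProbitFitError("complete control mortality; assay invalid")

    x = np.log10([r.dose for r in treated])
    n = np.array([r.n_exposed for r in treated], dtype=float)
    p = np.array([r.n_dead / r.n_exposed for r in treated])
    if p0 > 0:
        p = np.clip((p - p0) / (1.0 - p0), 0.0, 1.0)  # Abbott's correction
    if np.all(p == 1.0) or np.all(p == 0.0):
        raise ProbitFitError(
            f"{table.population}/{table.compound}: mortality is "
            f"{'complete' if p[0] == 1.0 else 'absent'} at every dose; "
            "no information on the LC50 — widen the dose range"
        )

    exog = sm.add_constant(x)
    model = sm.GLM(p, exog, family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=n)
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise ProbitFitError(
            f"{table.population}/{table.compound}: probit fit failed "
            f"({exc}); doses {doses}, mortalities {np.round(p, 3).tolist()}"
        ) from exc
    if not res.converged or not np.all(np.isfinite(res.params)):
        raise ProbitFitError(
            f"{table.population}/{table.compound}: probit fit did not converge; "
            f"doses {doses}, mortalities {np.round(p, 3).tolist()} "
            "(possible complete separation — widen the dose range)"
        )
    a, b = res.params
    if b <= 0:
        raise ProbitFitError(
            f"{table.population}/{table.compound}: fitted slope {b:.3g} is not "
            "positive; mortality does not increase with dose"
        )

    df = len(treated) - 2
    het = float(res.pearson_chi2 / df) if df > 0 else None
    if het is not None and het > 2:
        logger.warning(
            "%s/%s: heterogeneity chi2/df = %.2f > 2 (overdispersed fit)",
            table.population, table.compound, het,
        )

    fit = ProbitFit(
        intercept=float(a),
        slope=float(b),
        slope_se=float(res.bse[1]),
        lc50=float(10.0 ** ((norm.ppf(0.50) - a) / b)),
        lc90=float(10.0 ** ((norm.ppf(0.90) - a) / b)),
        lc95=float(10.0 ** ((norm.ppf(0.95) - a) / b)),
        converged=bool(res.converged),
        control_mortality=p0,
        heterogeneity=het,
    )
    return fit


def resistance_ratio(test: ProbitFit, reference: ProbitFit, q: float) -> float:
    """LCq of the test population divided by the reference strain's."""
    if not (test.converged and reference.converged):
        raise ValueError("both fits must have converged")
    return test.lc(q) / reference.lc(q)


def compute_resistance_ratios(
    test: ProbitFit, reference: ProbitFit, threshold: float = 3.0
) -> ResistanceRatio:
    rr50 = resistance_ratio(test, reference, 0.50)
    rr90 = resistance_ratio(test, reference, 0.90)
    rr95 = resistance_ratio(test, reference, 0.95)
    rr = ResistanceRatio(rr50, rr90, rr95, "")
    return ResistanceRatio(rr50, rr90, rr95, classify_resistance(rr, threshold))


def kdt_ratio(test_kdt: float, reference_kdt: float) -> float:
    """Knockdown-time ratio of test vs reference population."""
    if test_kdt <= 0 or reference_kdt <= 0:
        raise ValueError("knockdown times must be positive")
    return test_kdt / reference_kdt


def classify_resistance(
    rr: ResistanceRatio, threshold: float = 3.0, quantile: str = "rr95"
) -> str:
    """"resistant" iff the chosen quantile's ratio strictly exceeds the threshold."""
    value = getattr(rr, quantile)
    return "resistant" if value > threshold else "susceptible"
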