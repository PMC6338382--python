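"""Small shared statistical helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from statsmodels.stats.proportion import proportion_confint


def wilson_ci(count: int, nobs: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Stable at extreme frequencies (0 or 1 successes), which is the common
    regime for transmission-leakage and colony-QA screens.
    """
    if nobs <= 0:
        raise ValueError("nobs must be positive")
    if not 0 <= count <= nobs:
        raise ValueError(f"count {count} outside [0, {nobs}]")
    low, high = proportion_confint(count, nobs, alpha=1.0 - level, method="wilson")
    # statsmodels returns ~1e-18 instead of exact bounds at the extremes
    if count == 0:
        low = 0.0
    if count == nobs:
        high = 1.0
    return float(low), float(high)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report formatting only)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
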