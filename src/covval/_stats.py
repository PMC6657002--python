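"""Shared statistical helpers: interval estimates and report rounding."""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class EstimateCI:
    """A point estimate with a two-sided confidence interval on [0, 1]."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    def __iter__(self):
        return iter((self.estimate, self.lower, self.upper))


def proportion_ci(
    count: int, nobs: int, *, level: float = 0.95, method: str = "clopper-pearson"
) -> EstimateCI:
    """Binomial proportion with exact (Clopper-Pearson) or Wilson CI.

    Clopper-Pearson is the default: with count==nobs the upper bound is
    exactly 1 and the lower bound solves the exact tail equation, matching
    the "100 (99-100)" style bounds seen in validation reports.
    """
    if nobs <= 0:
        raise ValueError("proportion_ci requires nobs > 0")
    name = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if name is None:
        raise ValueError(f"unknown CI method: {method!r}")
    lower, upper = proportion_confint(count, nobs, alpha=1 - level, method=name)
    return EstimateCI(count / nobs, float(lower), float(upper), level)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention; Python's round is banker's)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
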