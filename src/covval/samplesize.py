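"""Precision-based sample size for validity studies.

For a target sensitivity Se estimated to within a half-width d at confidence
1 - alpha (normal approximation to the binomial), the number of
gold-positive births required is

    n_pos = ceil( z^2 * Se (1 - Se) / d^2 )

and analogously n_neg for specificity among gold-negative births.  Because
only a fraction ``prevalence`` of observed births is gold-positive, the
total observed sample must satisfy both margins:

    n_total = ceil( max(n_pos / prevalence, n_neg / (1 - prevalence)) ).

At the defaults (prevalence 0.5, Se 0.60, Sp 0.70, d 0.07, alpha 0.05) this
gives n_pos = 189, n_neg = 165 and a total of 378.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from covval.errors import ConfigurationError

__all__ = ["SampleSizeSpec", "required_n"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Planning assumptions for a precision-based validity sample size."""

    expected_prevalence: float = 0.5
    target_se: float = 0.60
    target_sp: float = 0.70
    precision: float = 0.07
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("expected_prevalence", "target_se", "target_sp"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {value}")
        if self.precision <= 0:
            raise ConfigurationError("precision must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")


def required_n(spec: SampleSizeSpec = SampleSizeSpec()) -> dict[str, int]:
    """Required gold-positive, gold-negative and total sample sizes."""
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    d2 = spec.precision**2
    n_pos = math.ceil(z * z * spec.target_se * (1.0 - spec.target_se) / d2)
    n_neg = math.ceil(z * z * spec.target_sp * (1.0 - spec.target_sp) / d2)
    n_total = math.ceil(
        max(n_pos / spec.expected_prevalence, n_neg / (1.0 - spec.expected_prevalence))
    )
    return {"n_for_se": n_pos, "n_for_sp": n_neg, "n_total": n_total}
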