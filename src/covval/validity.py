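"""Individual- and population-level validity metrics for binary indicators.

Individual-level reporting accuracy: sensitivity (true positive rate),
specificity (true negative rate) and the area under the receiver operating
characteristic curve, which for a single binary test is AUC = (Se + Sp)/2 —
0.5 is a random guess, 1 complete accuracy.

Population-level bias: the inflation factor (IF), the ratio of the estimated
population-based survey prevalence to the gold-standard prevalence, where

    estimated survey prevalence = P*Se + (1 - P)*(1 - Sp)

pushes the true prevalence P through the misclassification channel.  IF > 1
means a survey built on the comparison method would over-estimate coverage.

Validity cutoffs: AUC >= 0.70 (inclusive) for high individual-level
accuracy; 0.75 < IF < 1.25 (both strict) for low population-level bias;
"high overall validity" means both.

Confidence intervals: exact Clopper-Pearson for sensitivity, specificity and
unclustered prevalence (Wilson available behind a flag); a Wald combination
for the AUC, var(AUC) = [var(Se) + var(Sp)]/4 with normal quantiles
truncated to [0, 1]; and a cluster-robust (sandwich) logit-scale Wald
interval for facility-clustered prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from covval._stats import EstimateCI, proportion_ci, round_half_away
from covval.crosstab import (
    EligibilityResult,
    MatchedPairSet,
    TwoByTwoTable,
    build_two_by_two,
    eligibility,
    percent_agreement,
)
from covval.errors import ConfigurationError
from covval.indicators import TriState

__all__ = [
    "ValidityCriteria",
    "ValidityResult",
    "sensitivity",
    "specificity",
    "auc_binary",
    "estimated_survey_prevalence",
    "inflation_factor",
    "classify",
    "prevalence",
    "evaluate_matched_pairs",
]


@dataclass(frozen=True)
class ValidityCriteria:
    """Cutoffs used to classify indicator-method pairs."""

    auc_cutoff: float = 0.70  # inclusive
    if_lower: float = 0.75  # exclusive
    if_upper: float = 1.25  # exclusive
    min_cell: int = 5
    dk_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.if_lower < self.if_upper:
            raise ConfigurationError("if_lower must be below if_upper")


def sensitivity(
    table: TwoByTwoTable, *, level: float = 0.95, ci_method: str = "clopper-pearson"
) -> EstimateCI | None:
    """True positive rate a/(a+c) with exact binomial CI; None if a+c == 0."""
    n_pos = table.a + table.c
    if n_pos == 0:
        return None
    return proportion_ci(table.a, n_pos, level=level, method=ci_method)


def specificity(
    table: TwoByTwoTable, *, level: float = 0.95, ci_method: str = "clopper-pearson"
) -> EstimateCI | None:
    """True negative rate d/(b+d) with exact binomial CI; None if b+d == 0."""
    n_neg = table.b + table.d
    if n_neg == 0:
        return None
    return proportion_ci(table.d, n_neg, level=level, method=ci_method)


def auc_binary(
    se: float,
    sp: float,
    n_positive: int | None = None,
    n_negative: int | None = None,
    *,
    level: float = 0.95,
) -> EstimateCI:
    """AUC of a single binary test: (Se + Sp)/2.

    When the gold-positive and gold-negative sample sizes are given, a Wald
    interval is attached using var(AUC) = [Se(1-Se)/n_pos + Sp(1-Sp)/n_neg]/4,
    truncated to [0, 1]; otherwise the bounds are NaN.
    """
    for name, value in (("se", se), ("sp", sp)):
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
    auc = (se + sp) / 2.0
    if n_positive and n_negative:
        var = (se * (1 - se) / n_positive + sp * (1 - sp) / n_negative) / 4.0
        z = norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var)
        return EstimateCI(auc, max(0.0, auc - half), min(1.0, auc + half), level)
    return EstimateCI(auc, float("nan"), float("nan"), level)


def estimated_survey_prevalence(p_gold: float, se: float, sp: float) -> float:
    """Prevalence a survey using the comparison method would estimate."""
    if not 0.0 <= p_gold <= 1.0:
        raise ConfigurationError(f"p_gold must be in [0, 1], got {p_gold}")
    return p_gold * se + (1.0 - p_gold) * (1.0 - sp)


def inflation_factor(p_gold: float, se: float, sp: float) -> float | None:
    """Estimated survey prevalence over gold prevalence; None when P_gold = 0."""
    if p_gold == 0:
        return None
    return estimated_survey_prevalence(p_gold, se, sp) / p_gold


def classify(
    auc: float | None,
    inflation: float | None,
    criteria: ValidityCriteria = ValidityCriteria(),
) -> frozenset[str] | None:
    """Which validity criteria a (AUC, IF) pair meets.

    Returns a subset of {"AUC", "IF"} — AUC >= cutoff is inclusive, the IF
    band is strict on both sides — or None when either metric is undefined
    (ineligible).
    """
    if auc is None or inflation is None:
        return None
    met = set()
    if auc >= criteria.auc_cutoff:
        met.add("AUC")
    if criteria.if_lower < inflation < criteria.if_upper:
        met.add("IF")
    return frozenset(met)


def prevalence(
    values,
    cluster_labels=None,
    *,
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> EstimateCI | None:
    """Prevalence of a tri-state column, DK/missing excluded from the
    denominator.

    With ``cluster_labels`` (e.g. facility IDs) the CI is a logit-scale Wald
    interval with cluster-robust (sandwich) variance, reflecting
    within-facility correlation of care practices; it falls back to the
    exact binomial interval when the estimate is degenerate (0 or 1) or only
    one cluster is present.  Without labels the exact binomial CI is used.
    """
    values = pd.Series(list(values))
    codes = values.map(lambda v: v.value if isinstance(v, TriState) else str(v))
    assessed = codes.isin((TriState.POSITIVE.value, TriState.NEGATIVE.value))
    if not assessed.any():
        return None
    y = (codes[assessed] == TriState.POSITIVE.value).to_numpy(dtype=float)
    n, k = len(y), int(y.sum())
    if cluster_labels is None:
        return proportion_ci(k, n, level=level, method=ci_method)
    groups = pd.Series(list(cluster_labels))[assessed.to_numpy()].to_numpy()
    if k in (0, n) or len(np.unique(groups)) < 2:
        return proportion_ci(k, n, level=level, method=ci_method)
    import statsmodels.api as sm

    model = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial())
    fit = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    logit_p = float(fit.params[0])
    se_logit = float(fit.bse[0])
    z = norm.ppf(0.5 + level / 2.0)
    lo = 1.0 / (1.0 + math.exp(-(logit_p - z * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit_p + z * se_logit)))
    return EstimateCI(k / n, lo, hi, level)


@dataclass
class ValidityResult:
    """One report row: everything computed for an indicator-method pair."""

    indicator_id: str
    method: str
    n_gold_assessed: int
    gold_prevalence: EstimateCI | None
    n_comparison_assessed: int
    comparison_prevalence: EstimateCI | None
    n_pairs: int
    table: TwoByTwoTable | None
    agreement: float | None
    eligibility: EligibilityResult | None
    sensitivity: EstimateCI | None = None
    specificity: EstimateCI | None = None
    auc: EstimateCI | None = None
    estimated_prevalence: float | None = None
    inflation_factor: float | None = None
    criteria_met: frozenset[str] | None = None
    reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def criteria_label(self) -> str:
        """Presentation label: 'AUC,IF' / 'AUC' / 'IF' / 'none' / 'ineligible'."""
        if self.criteria_met is None:
            return "ineligible"
        if not self.criteria_met:
            return "none"
        return ",".join(sorted(self.criteria_met))


def evaluate_matched_pairs(
    pair_set: MatchedPairSet,
    criteria: ValidityCriteria = ValidityCriteria(),
    *,
    gold_values=None,
    gold_clusters=None,
    ci_method: str = "clopper-pearson",
) -> ValidityResult:
    """Run the full per-pair validity computation for one indicator-method.

    Builds the 2x2 table under the exclusion rules, gates it for
    eligibility, and — when eligible — computes Se, Sp, AUC, the estimated
    survey prevalence and the inflation factor, then classifies against
    ``criteria`` using full-precision values.

    ``gold_values``/``gold_clusters`` optionally supply the complete gold
    column (all observed births, not just matched ones) so the gold
    prevalence uses the full observation denominator, as a validation study
    would report it; by default the pair set's gold column is used.
    """
    pairs = pair_set.pairs
    table = build_two_by_two(pair_set)
    gate = eligibility(table, dk_threshold=criteria.dk_threshold, min_cell=criteria.min_cell)
    agreement = percent_agreement(table)

    if gold_values is None:
        gold_values = pairs["gold"]
        gold_clusters = pairs["facility_id"]
    gold_prev = prevalence(gold_values, gold_clusters, ci_method=ci_method)
    comp_prev = prevalence(
        pairs["comparison"], pairs["facility_id"], ci_method=ci_method
    )

    result = ValidityResult(
        indicator_id=pair_set.indicator_id,
        method=pair_set.method,
        n_gold_assessed=pair_set.n_gold_assessed,
        gold_prevalence=gold_prev,
        n_comparison_assessed=pair_set.n_comparison_assessed,
        comparison_prevalence=comp_prev,
        n_pairs=len(pair_set),
        table=table,
        agreement=agreement,
        eligibility=gate,
        reasons=gate.reasons,
    )
    if not gate.eligible_for_metrics:
        return result
    se = sensitivity(table, ci_method=ci_method)
    sp = specificity(table, ci_method=ci_method)
    result.sensitivity = se
    result.specificity = sp
    if se is None or sp is None or gold_prev is None:
        reasons = list(result.reasons)
        reasons.append("undefined-metric")
        result.reasons = tuple(reasons)
        return result
    result.auc = auc_binary(
        se.estimate, sp.estimate, table.a + table.c, table.b + table.d
    )
    p_gold = gold_prev.estimate
    result.estimated_prevalence = estimated_survey_prevalence(
        p_gold, se.estimate, sp.estimate
    )
    result.inflation_factor = inflation_factor(p_gold, se.estimate, sp.estimate)
    if result.inflation_factor is None:
        reasons = list(result.reasons)
        reasons.append("zero-gold-prevalence")
        result.reasons = tuple(reasons)
        return result
    result.criteria_met = classify(
        result.auc.estimate, result.inflation_factor, criteria
    )
    return result


def rounded_metrics(result: ValidityResult) -> dict[str, float | None]:
    """Report-granularity values: whole percents for Se/Sp/agreement, two
    decimals for AUC and IF (half away from zero)."""

    def pct(x):
        return None if x is None else round_half_away(100 * x, 0)

    return {
        "agreement_pct": pct(result.agreement),
        "sensitivity_pct": pct(result.sensitivity.estimate if result.sensitivity else None),
        "specificity_pct": pct(result.specificity.estimate if result.specificity else None),
        "auc": None if result.auc is None else round_half_away(result.auc.estimate, 2),
        "inflation_factor": None
        if result.inflation_factor is None
        else round_half_away(result.inflation_factor, 2),
    }
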