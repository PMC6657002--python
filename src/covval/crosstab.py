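"""Link gold and comparison records into matched pairs and build 2x2 tables.

A matched pair is one birth's gold-standard value linked, by observation ID,
to one comparison method's value for the same indicator.  Don't-know and
missing responses are excluded from the 2x2 cells but tallied, so the
conservation identity ``a+b+c+d + exclusions == pairs`` always holds.

Eligibility for validity metrics follows the study's two gates: at least
five observations in every cell of the 2x2 table, and a don't-know rate of
at most 5% among comparison responses.  Both gates are always evaluated so
reports can show which one(s) failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from covval.catalogue import METHODS
from covval.errors import DataError
from covval.indicators import TriState, to_tristate

__all__ = [
    "MatchedPairSet",
    "TwoByTwoTable",
    "EligibilityResult",
    "link_pairs",
    "build_two_by_two",
    "percent_agreement",
    "eligibility",
]

_POS = TriState.POSITIVE.value
_NEG = TriState.NEGATIVE.value
_DK = TriState.DONT_KNOW.value
_NA = TriState.MISSING.value


@dataclass
class MatchedPairSet:
    """Linked gold/comparison values for one indicator-method comparison.

    ``pairs`` has columns ``observation_id, facility_id, round_id, gold,
    comparison`` with string codes ``"1"/"0"/"DK"/"NA"``; the gold column is
    never ``"DK"``.
    """

    indicator_id: str
    method: str
    pairs: pd.DataFrame
    n_gold_assessed: int = 0
    n_comparison_assessed: int = 0

    def __post_init__(self) -> None:
        if self.pairs["observation_id"].duplicated().any():
            dupes = sorted(
                self.pairs.loc[
                    self.pairs["observation_id"].duplicated(), "observation_id"
                ].unique()
            )
            raise DataError(f"duplicate observation_id(s) in pair set: {dupes[:10]}")
        if (self.pairs["gold"] == _DK).any():
            bad = self.pairs.loc[self.pairs["gold"] == _DK, "observation_id"]
            raise DataError(
                f"gold standard carries don't-know for observation(s) {list(bad[:10])}"
            )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 counts plus exclusion tallies for one indicator-method pair.

    a: both positive (TP); b: gold negative, comparison positive (FP);
    c: gold positive, comparison negative (FN); d: both negative (TN).
    """

    a: int
    b: int
    c: int
    d: int
    n_excluded_dk: int = 0
    n_excluded_missing: int = 0
    dk_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 cell counts must be non-negative")

    @property
    def n_classified(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_pairs(self) -> int:
        """Pairs presented, including exclusions (conservation identity)."""
        return self.n_classified + self.n_excluded_dk + self.n_excluded_missing

    @property
    def min_cell(self) -> int:
        return min(self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EligibilityResult:
    eligible_for_metrics: bool
    reasons: tuple[str, ...] = ()


def link_pairs(cohort: pd.DataFrame, indicator_id: str, method: str) -> MatchedPairSet:
    """Link gold rows to one method's rows on observation ID.

    One pair per birth that has both a gold value and a method row; births
    lacking the method row are counted in ``n_gold_assessed`` but not
    paired.  Duplicate observation IDs within a source are a data error.
    """
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}")
    if indicator_id not in cohort.columns:
        raise DataError(f"cohort has no column for indicator {indicator_id!r}")
    keys = ["observation_id", "facility_id", "round_id"]
    gold = cohort.loc[cohort["source"] == "gold", keys + [indicator_id]]
    comp = cohort.loc[cohort["source"] == method, ["observation_id", indicator_id]]
    for name, df in (("gold", gold), (method, comp)):
        if df["observation_id"].duplicated().any():
            dupes = sorted(
                df.loc[df["observation_id"].duplicated(), "observation_id"].unique()
            )
            raise DataError(
                f"duplicate observation_id(s) in source {name!r}: {dupes[:10]}"
            )
    gold = gold.rename(columns={indicator_id: "gold"})
    comp = comp.rename(columns={indicator_id: "comparison"})
    pairs = gold.merge(comp, on="observation_id", how="inner")
    pairs = pairs.reset_index(drop=True)
    n_gold = int((gold["gold"].isin((_POS, _NEG))).sum())
    n_comp = int((comp["comparison"].isin((_POS, _NEG, _DK))).sum())
    return MatchedPairSet(
        indicator_id=indicator_id,
        method=method,
        pairs=pairs,
        n_gold_assessed=n_gold,
        n_comparison_assessed=n_comp,
    )


def build_two_by_two(pair_set: MatchedPairSet) -> TwoByTwoTable:
    """Tabulate matched pairs into a 2x2 table under the exclusion rules.

    A gold-side missing value drops the pair (truth cannot be classified);
    a comparison don't-know or missing drops the pair; every exclusion is
    tallied.  The don't-know rate is computed over comparison *responses*
    (pairs whose comparison value is not missing) before exclusion.
    """
    gold = pair_set.pairs["gold"]
    comp = pair_set.pairs["comparison"]
    gold_ok = gold.isin((_POS, _NEG))
    comp_na = comp == _NA
    comp_dk = comp == _DK
    # bucket assignment: gold-missing first, then comparison-missing, then DK
    missing = (~gold_ok) | (gold_ok & comp_na)
    dk = gold_ok & ~comp_na & comp_dk
    keep = gold_ok & ~comp_na & ~comp_dk
    a = int(((gold == _POS) & (comp == _POS) & keep).sum())
    b = int(((gold == _NEG) & (comp == _POS) & keep).sum())
    c = int(((gold == _POS) & (comp == _NEG) & keep).sum())
    d = int(((gold == _NEG) & (comp == _NEG) & keep).sum())
    n_responses = int((~comp_na).sum())
    dk_rate = float(comp_dk.sum() / n_responses) if n_responses else 0.0
    return TwoByTwoTable(
        a=a,
        b=b,
        c=c,
        d=d,
        n_excluded_dk=int(dk.sum()),
        n_excluded_missing=int(missing.sum()),
        dk_rate=dk_rate,
    )


def percent_agreement(table: TwoByTwoTable) -> float | None:
    """Observed agreement (a+d)/(a+b+c+d); None for an empty table."""
    n = table.n_classified
    if n == 0:
        return None
    return (table.a + table.d) / n


def eligibility(
    table: TwoByTwoTable,
    dk_threshold: float = 0.05,
    min_cell: int = 5,
) -> EligibilityResult:
    """Gate a table for validity metrics.

    Eligible iff every cell holds at least ``min_cell`` observations
    (boundary inclusive) and the don't-know rate does not exceed
    ``dk_threshold``.  Both gates are evaluated even when the first fails.
    """
    reasons = []
    if table.min_cell < min_cell:
        reasons.append("cell-count")
    if table.dk_rate > dk_threshold:
        reasons.append("dk-rate")
    return EligibilityResult(eligible_for_metrics=not reasons, reasons=tuple(reasons))


def pairs_from_values(values, indicator_id: str = "ind", method: str = "exit") -> MatchedPairSet:
    """Build a pair set from (gold, comparison) value tuples — test/fixture aid."""
    rows = []
    for i, (g, c) in enumerate(values):
        rows.append(
            {
                "observation_id": f"OBS-{i:05d}",
                "facility_id": "F01",
                "round_id": "R1",
                "gold": to_tristate(g).value,
                "comparison": to_tristate(c).value,
            }
        )
    cols = ["observation_id", "facility_id", "round_id", "gold", "comparison"]
    pairs = pd.DataFrame(rows, columns=cols)
    n_gold = int(pairs["gold"].isin((_POS, _NEG)).sum()) if rows else 0
    n_comp = int(pairs["comparison"].isin((_POS, _NEG, _DK)).sum()) if rows else 0
    return MatchedPairSet(indicator_id, method, pairs, n_gold, n_comp)
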