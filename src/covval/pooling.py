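"""Poolability screen: marginal homogeneity across data-collection rounds.

Before pooling rounds, each indicator-method comparison is screened with a
cluster-adjusted McNemar test for clustered binary matched-pair data.  With
per-cluster discordant counts b_k (gold negative / comparison positive) and
c_k (gold positive / comparison negative), the statistic is

    T = [sum_k (b_k - c_k)]^2 / sum_k (b_k - c_k)^2

referred to chi-square with 1 df (the Durkalski/Yang form: the denominator
is an empirical between-cluster variance estimate needing only per-cluster
discordant counts).  With singleton clusters (n_k = 1) it reduces exactly to
the classical McNemar statistic (b - c)^2/(b + c).

Under cluster replication the statistic is *not* invariant: duplicating
every cluster multiplies the numerator by 4 and the denominator by 2,
doubling T — the documented behaviour of this variance form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

from covval.catalogue import METHODS, Catalogue
from covval.crosstab import MatchedPairSet, build_two_by_two, link_pairs
from covval.errors import ConfigurationError, DataError

__all__ = [
    "ClusteredPairData",
    "ClusteredTestResult",
    "PoolabilityScreen",
    "clustered_mcnemar",
    "poolability_screen",
]


@dataclass(frozen=True)
class ClusterCounts:
    cluster_id: str
    b_k: int  # gold negative, comparison positive
    c_k: int  # gold positive, comparison negative
    n_k: int  # classified pairs in the cluster

    def __post_init__(self) -> None:
        if min(self.b_k, self.c_k) < 0 or self.b_k + self.c_k > self.n_k:
            raise DataError(
                f"cluster {self.cluster_id!r}: need 0 <= b_k + c_k <= n_k, "
                f"got b={self.b_k}, c={self.c_k}, n={self.n_k}"
            )


@dataclass(frozen=True)
class ClusteredPairData:
    """Per-cluster discordant counts for one indicator-method comparison."""

    clusters: tuple[ClusterCounts, ...]

    @classmethod
    def from_counts(cls, counts: Sequence[tuple[str, int, int, int]]) -> "ClusteredPairData":
        return cls(tuple(ClusterCounts(*row) for row in counts))


@dataclass(frozen=True)
class ClusteredTestResult:
    statistic: float
    p_value: float
    df: int = 1
    degenerate: bool = False
    variant: str = "durkalski-yang"


def clustered_mcnemar(data: ClusteredPairData) -> ClusteredTestResult:
    """Cluster-adjusted McNemar test of marginal homogeneity.

    Requires at least two clusters (with one cluster there is nothing to
    adjust for — use the classical McNemar test instead).  When no
    discordant pairs exist the result is statistic 0, p = 1, flagged
    degenerate; when discordance balances exactly within every cluster the
    statistic is 0 with p = 1.
    """
    if len(data.clusters) < 2:
        raise ConfigurationError(
            "clustered test needs >= 2 clusters; with a single cluster use the "
            "classical McNemar test"
        )
    diffs = [k.b_k - k.c_k for k in data.clusters]
    total_discordant = sum(k.b_k + k.c_k for k in data.clusters)
    denom = float(sum(d * d for d in diffs))
    if total_discordant == 0:
        return ClusteredTestResult(0.0, 1.0, degenerate=True)
    if denom == 0.0:
        return ClusteredTestResult(0.0, 1.0)
    stat = float(sum(diffs)) ** 2 / denom
    return ClusteredTestResult(stat, float(chi2.sf(stat, 1)))


def pool_recommendation(n_flagged: int, n_tested: int, alpha: float) -> str:
    """Overall pool/no-pool call: "combine" when the flag count does not
    exceed the number chance alone would produce (``ceil(alpha * n_tested)``),
    else "review"."""
    allowance = math.ceil(alpha * n_tested) if n_tested else 0
    return "combine" if n_flagged <= allowance else "review"


@dataclass
class PoolabilityScreen:
    """Screen results across all indicator-method comparisons."""

    table: pd.DataFrame
    alpha: float
    n_tested: int
    n_flagged: int
    recommendation: str  # "combine" or "review"


def _cluster_counts(pair_set: MatchedPairSet, cluster_by: str) -> ClusteredPairData:
    rows = []
    for cluster_id, chunk in pair_set.pairs.groupby(cluster_by, sort=True):
        sub = MatchedPairSet(
            pair_set.indicator_id,
            pair_set.method,
            chunk.reset_index(drop=True),
        )
        t = build_two_by_two(sub)
        rows.append(ClusterCounts(str(cluster_id), t.b, t.c, t.n_classified))
    return ClusteredPairData(tuple(rows))


def poolability_screen(
    cohort: pd.DataFrame,
    catalogue: Catalogue,
    alpha: float = 0.05,
    *,
    cluster_by: str = "round_id",
) -> PoolabilityScreen:
    """Run the clustered test per indicator-method, clustering by round.

    Flags (never drops) comparisons whose p-value falls below ``alpha``.
    The overall recommendation is "combine" when the number of flags does
    not exceed what chance alone would produce across the screens
    (``ceil(alpha * n_tested)``), mirroring the narrative decision logic of
    validation studies; otherwise "review".  ``cluster_by="facility_id"``
    or any other cohort column is accepted.
    """
    present = set(cohort.loc[cohort["source"] != "gold", "source"].unique())
    rows = []
    for definition in catalogue:
        for method in METHODS:
            if method not in definition.methods_assessed or method not in present:
                continue
            record: dict = {"indicator_id": definition.indicator_id, "method": method}
            try:
                pair_set = link_pairs(cohort, definition.indicator_id, method)
            except DataError as exc:
                record.update(status=f"skipped: {exc}", n_clusters=0)
                rows.append(record)
                continue
            if len(pair_set) == 0:
                record.update(status="skipped: no pairs", n_clusters=0)
                rows.append(record)
                continue
            data = _cluster_counts(pair_set, cluster_by)
            if len(data.clusters) < 2:
                record.update(status="skipped: single cluster", n_clusters=len(data.clusters))
                rows.append(record)
                continue
            result = clustered_mcnemar(data)
            record.update(
                status="degenerate" if result.degenerate else "tested",
                n_clusters=len(data.clusters),
                statistic=result.statistic,
                p_value=result.p_value,
                flagged=(not result.degenerate) and result.p_value < alpha,
                variant=result.variant,
            )
            rows.append(record)
    table = pd.DataFrame(rows)
    tested = table.loc[table["status"].isin(("tested", "degenerate"))] if len(table) else table
    n_tested = len(tested)
    n_flagged = int(tested["flagged"].eq(True).sum()) if n_tested else 0
    recommendation = pool_recommendation(n_flagged, n_tested, alpha)
    return PoolabilityScreen(
        table=table,
        alpha=alpha,
        n_tested=n_tested,
        n_flagged=n_flagged,
        recommendation=recommendation,
    )
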