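"""Assemble per-indicator validity results into study-report artifacts.

``run_pipeline`` drives the end-to-end analysis: validate the cohort, screen
rounds for poolability, then for every indicator-method comparison link the
matched pairs, build the 2x2 table, gate eligibility, compute the validity
metrics and classify.  The resulting :class:`StudyReport` carries a
results table (one row per indicator-method), a criteria matrix (indicator
by method, with a fixed cell vocabulary), per-method headline counts and
provenance.

Report formatting follows validation-study convention: prevalence,
agreement, sensitivity and specificity as whole percents with their CIs,
AUC and inflation factor to two decimals (half away from zero); unrounded
values are preserved in the underlying result objects and the JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from covval._stats import EstimateCI, round_half_away
from covval.catalogue import METHODS, Catalogue, load_default_catalogue
from covval.crosstab import link_pairs
from covval.errors import DataError
from covval.indicators import TriState
from covval.pooling import PoolabilityScreen, poolability_screen
from covval.synthetic import read_cohort
from covval.validity import (
    ValidityCriteria,
    ValidityResult,
    evaluate_matched_pairs,
    rounded_metrics,
)

__all__ = ["StudyReport", "run_pipeline", "headline_counts", "validate_cohort"]

#: Fixed vocabulary of criteria-matrix cells.
MATRIX_CELLS = ("AUC+IF", "AUC", "IF", "none", ">5%dk", "<5/cell", "not assessed")

_VALID_CODES = {t.value for t in TriState}


def validate_cohort(cohort: pd.DataFrame, catalogue: Catalogue) -> tuple[pd.DataFrame, int]:
    """Coerce indicator codes, counting unparseable rows.

    Unknown codes become missing and the row is counted as unparseable;
    more than 10% unparseable rows aborts with a data error.
    """
    required = {"observation_id", "facility_id", "round_id", "source"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise DataError(f"cohort is missing columns: {sorted(missing_cols)}")
    indicator_cols = [d.indicator_id for d in catalogue if d.indicator_id in cohort.columns]
    cohort = cohort.copy()
    bad_rows = pd.Series(False, index=cohort.index)
    for col in indicator_cols:
        codes = cohort[col].astype(str).str.strip()
        codes = codes.replace({"nan": "NA", "": "NA", "dk": "DK", "na": "NA"})
        ok = codes.isin(_VALID_CODES)
        bad_rows |= ~ok
        cohort[col] = codes.where(ok, TriState.MISSING.value)
    n_bad = int(bad_rows.sum())
    if len(cohort) and n_bad / len(cohort) > 0.10:
        raise DataError(
            f"{n_bad} of {len(cohort)} cohort rows unparseable (>10%); aborting"
        )
    return cohort, n_bad


def _fmt_pct_ci(est: EstimateCI | None) -> str:
    if est is None:
        return ""
    p = int(round_half_away(100 * est.estimate, 0))
    lo = int(round_half_away(100 * est.lower, 0))
    hi = int(round_half_away(100 * est.upper, 0))
    return f"{p} ({lo}-{hi})"


def _fmt2_ci(est: EstimateCI | None) -> str:
    if est is None:
        return ""
    out = f"{round_half_away(est.estimate, 2):.2f}"
    if est.lower == est.lower:  # not NaN
        out += f" ({round_half_away(est.lower, 2):.2f}-{round_half_away(est.upper, 2):.2f})"
    return out


def _matrix_cell(result: ValidityResult | None) -> str:
    if result is None or result.n_pairs == 0:
        return "not assessed"
    if result.table is not None and result.table.n_classified + result.table.n_excluded_dk == 0:
        return "not assessed"  # pairs exist but the method reported nothing
    if result.criteria_met is not None:
        if result.criteria_met == frozenset({"AUC", "IF"}):
            return "AUC+IF"
        if result.criteria_met:
            return next(iter(result.criteria_met))
        return "none"
    if "cell-count" in result.reasons:
        return "<5/cell"
    if "dk-rate" in result.reasons:
        return ">5%dk"
    return "not assessed"


def headline_counts(
    results: list[ValidityResult], criteria: ValidityCriteria = ValidityCriteria()
) -> dict[str, dict[str, int]]:
    """Per-method counts of indicators meeting both, one, or neither
    criterion, with denominators = indicators assessed by that method."""
    out: dict[str, dict[str, int]] = {}
    for method in METHODS:
        rows = [r for r in results if r.method == method]
        if not rows:
            continue
        both = sum(1 for r in rows if r.criteria_met == frozenset({"AUC", "IF"}))
        one = sum(
            1 for r in rows if r.criteria_met is not None and len(r.criteria_met) == 1
        )
        neither = sum(1 for r in rows if r.criteria_met == frozenset())
        out[method] = {
            "n_assessed": len(rows),
            "n_both_criteria": both,
            "n_one_criterion": one,
            "n_neither": neither,
            "n_ineligible": sum(1 for r in rows if r.criteria_met is None),
        }
    return out


@dataclass
class StudyReport:
    """Assembled study outputs with stable ordering and formatting."""

    results: list[ValidityResult]
    catalogue: Catalogue
    criteria: ValidityCriteria
    pooling: PoolabilityScreen | None = None
    n_unparseable: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def headline(self) -> dict[str, dict[str, int]]:
        return headline_counts(self.results, self.criteria)

    def table3(self) -> pd.DataFrame:
        """One formatted row per indicator-method, in catalogue order."""
        by_key = {(r.indicator_id, r.method): r for r in self.results}
        rows = []
        for definition in self.catalogue:
            for method in METHODS:
                r = by_key.get((definition.indicator_id, method))
                if r is None:
                    continue
                metrics = rounded_metrics(r)
                rows.append(
                    {
                        "indicator_id": r.indicator_id,
                        "label": definition.label,
                        "group": definition.group,
                        "method": method,
                        "gold_n": r.n_gold_assessed,
                        "gold_prevalence": _fmt_pct_ci(r.gold_prevalence),
                        "comparison_n": r.n_comparison_assessed,
                        "dont_know_pct": int(
                            round_half_away(100 * (r.table.dk_rate if r.table else 0.0), 0)
                        ),
                        "comparison_prevalence": _fmt_pct_ci(r.comparison_prevalence),
                        "matched_pairs_n": r.n_pairs,
                        "agreement_pct": (
                            None if metrics["agreement_pct"] is None
                            else int(metrics["agreement_pct"])
                        ),
                        "five_per_cell": (
                            "yes" if r.table and r.table.min_cell >= self.criteria.min_cell else "no"
                        ),
                        "sensitivity": _fmt_pct_ci(r.sensitivity),
                        "specificity": _fmt_pct_ci(r.specificity),
                        "auc": _fmt2_ci(r.auc),
                        "inflation_factor": (
                            "" if metrics["inflation_factor"] is None
                            else f"{metrics['inflation_factor']:.2f}"
                        ),
                        "criteria_met": r.criteria_label,
                    }
                )
        return pd.DataFrame(rows)

    def figure2_matrix(self) -> pd.DataFrame:
        """Indicator x method criteria matrix with the fixed cell vocabulary."""
        by_key = {(r.indicator_id, r.method): r for r in self.results}
        rows = []
        for definition in self.catalogue:
            cells = {"indicator_id": definition.indicator_id}
            for method in METHODS:
                if method not in definition.methods_assessed:
                    cells[method] = "not assessed"
                else:
                    cells[method] = _matrix_cell(by_key.get((definition.indicator_id, method)))
            rows.append(cells)
        return pd.DataFrame(rows).set_index("indicator_id")

    def to_json_dict(self) -> dict:
        """Nested full-precision results (report parity lives in table3)."""
        out = []
        for r in self.results:
            def ci(est: EstimateCI | None):
                if est is None:
                    return None
                return {"estimate": est.estimate, "lower": est.lower, "upper": est.upper}

            out.append(
                {
                    "indicator_id": r.indicator_id,
                    "method": r.method,
                    "n_gold_assessed": r.n_gold_assessed,
                    "n_comparison_assessed": r.n_comparison_assessed,
                    "n_pairs": r.n_pairs,
                    "table": None
                    if r.table is None
                    else {
                        "a": r.table.a,
                        "b": r.table.b,
                        "c": r.table.c,
                        "d": r.table.d,
                        "n_excluded_dk": r.table.n_excluded_dk,
                        "n_excluded_missing": r.table.n_excluded_missing,
                        "dk_rate": r.table.dk_rate,
                    },
                    "gold_prevalence": ci(r.gold_prevalence),
                    "comparison_prevalence": ci(r.comparison_prevalence),
                    "agreement": r.agreement,
                    "sensitivity": ci(r.sensitivity),
                    "specificity": ci(r.specificity),
                    "auc": ci(r.auc),
                    "estimated_prevalence": r.estimated_prevalence,
                    "inflation_factor": r.inflation_factor,
                    "criteria_met": r.criteria_label,
                    "reasons": list(r.reasons),
                }
            )
        return {
            "results": out,
            "headline": self.headline,
            "n_unparseable_rows": self.n_unparseable,
            "provenance": self.provenance,
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table3().to_csv(out / "validity_table.csv", index=False)
        self.figure2_matrix().to_csv(out / "criteria_matrix.csv")
        if self.pooling is not None:
            self.pooling.table.to_csv(out / "poolability.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def run_pipeline(
    cohort: pd.DataFrame | str | Path,
    catalogue: Catalogue | None = None,
    criteria: ValidityCriteria = ValidityCriteria(),
    *,
    alpha: float = 0.05,
    ci_method: str = "clopper-pearson",
    provenance: dict | None = None,
) -> StudyReport:
    """Run the full validation analysis over a cohort.

    ``cohort`` may be a DataFrame or a CSV path (long format, one row per
    source per birth).  Indicators appear in the report when the catalogue
    says the method assesses them and the cohort carries any data for the
    pair; skipped computations carry a reason code.  An empty cohort yields
    an empty report without failing.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = read_cohort(cohort)
    if catalogue is None:
        catalogue = load_default_catalogue()
    from covval import __version__

    prov = dict(provenance or {})
    prov.setdefault("software_version", __version__)
    prov.setdefault("criteria", vars(criteria).copy())

    if len(cohort) == 0:
        return StudyReport([], catalogue, criteria, provenance=prov)

    cohort, n_bad = validate_cohort(cohort, catalogue)
    screen = None
    if cohort["round_id"].nunique() >= 2:
        screen = poolability_screen(cohort, catalogue, alpha=alpha)

    present = set(cohort.loc[cohort["source"] != "gold", "source"].unique())
    gold_rows = cohort.loc[cohort["source"] == "gold"]
    results: list[ValidityResult] = []
    for definition in catalogue:
        ind = definition.indicator_id
        if ind not in cohort.columns:
            continue
        gold_values = gold_rows[ind]
        gold_clusters = gold_rows["facility_id"]
        for method in METHODS:
            if method not in definition.methods_assessed or method not in present:
                continue
            pair_set = link_pairs(cohort, ind, method)
            if len(pair_set) == 0:
                continue
            results.append(
                evaluate_matched_pairs(
                    pair_set,
                    criteria,
                    gold_values=gold_values,
                    gold_clusters=gold_clusters,
                    ci_method=ci_method,
                )
            )
    return StudyReport(
        results,
        catalogue,
        criteria,
        pooling=screen,
        n_unparseable=n_bad,
        provenance=prov,
    )
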