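"""Published point estimates from the Gombe State childbirth-care validation
study, shipped as a package resource.

One row per indicator-method comparison (45 rows): gold-standard denominator
and prevalence, comparison denominator, don't-know percentage, comparison
prevalence, matched-pair count, percent agreement, the five-per-cell
eligibility flag, and — where the study reported them — sensitivity,
specificity, AUC, inflation factor and the validity criteria met.  Percent
columns are whole percents as published; AUC and IF carry two decimals.

These values serve as (i) cross-check fixtures for the metric and
classification functions and (ii) generative defaults for
:meth:`covval.synthetic.SyntheticCohortConfig.from_reference`, which emulates
the study's measurement-error conditions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_estimates() -> pd.DataFrame:
    """Load the published estimates table.

    Returns a DataFrame with columns ``indicator_id, method, gold_n,
    gold_prevalence_pct, comparison_n, dont_know_pct,
    comparison_prevalence_pct, matched_pairs_n, agreement_pct, five_per_cell,
    sensitivity_pct, specificity_pct, auc, inflation_factor, criteria_met``.
    Metric columns are NaN for rows the study left unreported (sparse cells
    or >5% don't-know); ``criteria_met`` is the published label ("AUC,IF",
    "AUC", "IF" or "none") and NaN where no metrics were reported.
    """
    with resources.files("covval.data").joinpath("reference_estimates.csv").open(
        "rb"
    ) as fh:
        df = pd.read_csv(fh)
    df["five_per_cell"] = df["five_per_cell"].map({"yes": True, "no": False})
    return df
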