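"""Sensitivity, specificity, AUC, inflation factor, classification, prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta

from covval._stats import proportion_ci, round_half_away
from covval.crosstab import TwoByTwoTable
from covval.errors import ConfigurationError
from covval.validity import (
    ValidityCriteria,
    auc_binary,
    classify,
    estimated_survey_prevalence,
    inflation_factor,
    prevalence,
    sensitivity,
    specificity,
)


def clopper_pearson_oracle(k, n, level=0.95):
    """Beta-quantile form of the exact binomial interval."""
    alpha = 1 - level
    lo = 0.0 if k == 0 else beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else beta.ppf(1 - alpha / 2, k + 1, n - k)
    return lo, hi


class TestSensitivitySpecificity:
    def test_perfect_sensitivity(self):
        est = sensitivity(TwoByTwoTable(10, 0, 0, 0))
        assert est.estimate == 1.0 and est.upper == 1.0

    def test_sensitivity_with_exact_ci(self):
        est = sensitivity(TwoByTwoTable(34, 0, 7, 0))
        assert est.estimate == pytest.approx(34 / 41, abs=5e-4)  # 0.829
        lo, hi = clopper_pearson_oracle(34, 41)
        assert est.lower == pytest.approx(lo, abs=1e-9)
        assert est.upper == pytest.approx(hi, abs=1e-9)

    def test_zero_sensitivity(self):
        est = sensitivity(TwoByTwoTable(0, 0, 10, 0))
        assert est.estimate == 0.0 and est.lower == 0.0

    def test_sensitivity_undefined_without_gold_positives(self):
        assert sensitivity(TwoByTwoTable(0, 3, 0, 7)) is None

    def test_specificity_values(self):
        assert specificity(TwoByTwoTable(0, 15, 0, 85)).estimate == pytest.approx(0.85)
        assert specificity(TwoByTwoTable(0, 8, 0, 8)).estimate == pytest.approx(0.5)
        assert specificity(TwoByTwoTable(0, 0, 0, 20)).estimate == 1.0
        assert specificity(TwoByTwoTable(5, 0, 5, 0)) is None

    def test_wilson_flag(self):
        exact = sensitivity(TwoByTwoTable(34, 0, 7, 0))
        wilson = sensitivity(TwoByTwoTable(34, 0, 7, 0), ci_method="wilson")
        assert exact.estimate == wilson.estimate
        assert exact.lower != wilson.lower  # different interval families


class TestAUC:
    @pytest.mark.parametrize(
        ("se", "sp", "expected"),
        [(0.92, 0.98, 0.95), (0.5, 0.5, 0.50), (0.82, 1.00, 0.91)],
    )
    def test_point_values(self, se, sp, expected):
        assert auc_binary(se, sp).estimate == pytest.approx(expected)

    def test_ci_from_binomial_variances(self):
        est = auc_binary(0.8, 0.9, n_positive=100, n_negative=400)
        half = 1.959963984540054 * np.sqrt(
            (0.8 * 0.2 / 100 + 0.9 * 0.1 / 400) / 4
        )
        assert est.lower == pytest.approx(0.85 - half)
        assert est.upper == pytest.approx(0.85 + half)

    def test_ci_truncated_to_unit_interval(self):
        est = auc_binary(0.99, 0.99, n_positive=5, n_negative=5)
        assert 0.0 <= est.lower and est.upper <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigurationError):
            auc_binary(1.2, 0.5)


class TestSurveyPrevalenceAndIF:
    def test_perfect_test_is_identity(self):
        for p in (0.0, 0.3, 1.0):
            assert estimated_survey_prevalence(p, 1.0, 1.0) == pytest.approx(p)

    def test_arithmetic_example(self):
        assert estimated_survey_prevalence(0.77, 0.94, 0.93) == pytest.approx(0.7399)

    def test_uninformative_test_gives_half(self):
        for p in (0.1, 0.5, 0.9):
            assert estimated_survey_prevalence(p, 0.5, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        ("p", "se", "sp", "expected"),
        [(0.77, 0.94, 0.93, 0.96), (0.49, 0.94, 0.87, 1.08), (0.5, 1.0, 1.0, 1.00)],
    )
    def test_if_examples(self, p, se, sp, expected):
        assert round_half_away(inflation_factor(p, se, sp), 2) == pytest.approx(expected)

    def test_if_undefined_at_zero_prevalence(self):
        assert inflation_factor(0.0, 0.9, 0.9) is None


@given(
    se=st.floats(0, 1), sp=st.floats(0, 1), p=st.floats(0.01, 1)
)
@settings(max_examples=200, derandomize=True)
def test_auc_and_if_identities(se, sp, p):
    """AUC == (Se+Sp)/2 and IF * P_gold == estimated survey prevalence."""
    assert auc_binary(se, sp).estimate == (se + sp) / 2
    inf = inflation_factor(p, se, sp)
    assert inf * p == pytest.approx(estimated_survey_prevalence(p, se, sp), abs=1e-12)


def test_if_monotone_decreasing_in_specificity():
    """Over a parameter grid, IF strictly decreases as Sp rises."""
    for p in (0.1, 0.3, 0.5, 0.8):
        for se in (0.6, 0.9):
            values = [inflation_factor(p, se, sp) for sp in np.linspace(0.1, 0.99, 12)]
            assert all(x > y for x, y in zip(values, values[1:]))


class TestClassify:
    @pytest.mark.parametrize(
        ("auc", "inf", "expected"),
        [
            (0.95, 1.05, {"AUC", "IF"}),
            (0.58, 3.76, set()),
            (0.70, 1.25, {"AUC"}),  # AUC boundary in, IF boundary out
            (0.69, 1.00, {"IF"}),
            (0.70, 0.75, {"AUC"}),  # lower IF bound also exclusive
        ],
    )
    def test_boundaries(self, auc, inf, expected):
        assert classify(auc, inf) == frozenset(expected)

    def test_undefined_metrics_are_ineligible(self):
        assert classify(None, 1.0) is None
        assert classify(0.9, None) is None

    def test_criteria_must_be_ordered(self):
        with pytest.raises(ConfigurationError):
            ValidityCriteria(if_lower=1.3, if_upper=1.2)


class TestPrevalence:
    def test_all_positive_single_cluster(self):
        est = prevalence(["1"] * 20, ["F01"] * 20)
        assert est.estimate == 1.0

    def test_unclustered_matches_beta_oracle(self):
        values = ["1"] * 50 + ["0"] * 450
        est = prevalence(values)
        assert est.estimate == pytest.approx(0.10)
        lo, hi = clopper_pearson_oracle(50, 500)
        assert est.lower == pytest.approx(lo, abs=1e-9)
        assert est.upper == pytest.approx(hi, abs=1e-9)

    def test_dk_and_missing_excluded_from_denominator(self):
        est = prevalence(["1", "0", "DK", "NA", "1"])
        assert est.estimate == pytest.approx(2 / 3)

    def test_empty_undefined(self):
        assert prevalence(["DK", "NA"]) is None

    def test_clustered_ci_wider_than_naive(self):
        rng = np.random.default_rng(11)
        values, clusters = [], []
        # strongly clustered: facility prevalences spread across [0.1, 0.9]
        for f, pf in enumerate(np.linspace(0.1, 0.9, 10)):
            draws = rng.random(100) < pf
            values.extend("1" if v else "0" for v in draws)
            clusters.extend([f"F{f:02d}"] * 100)
        clustered = prevalence(values, clusters)
        naive = prevalence(values)
        assert (clustered.upper - clustered.lower) > (naive.upper - naive.lower)

    def test_proportion_ci_rejects_bad_input(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(1, 10, method="bayes")
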