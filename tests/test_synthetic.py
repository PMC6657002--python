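"""Generative properties of the synthetic cohort module."""

import io

import numpy as np
import pandas as pd
import pytest

from covval.crosstab import build_two_by_two, link_pairs
from covval.errors import ConfigurationError
from covval.synthetic import (
    IndicatorModel,
    MethodErrorProfile,
    SyntheticCohortConfig,
    simulate_cohort,
    subsample_followup,
    write_cohort,
)


def single_indicator_config(
    p=0.5, se=1.0, sp=1.0, dk=0.0, miss=0.0, *, births=200, seed=0, **kwargs
):
    return SyntheticCohortConfig(
        indicators={
            "ind": IndicatorModel(
                p, {"exit": MethodErrorProfile(se, sp, dk, miss)}
            )
        },
        rounds=kwargs.pop("rounds", ("R1",)),
        births_per_facility_round=births,
        facility_effect_sd=kwargs.pop("facility_effect_sd", 0.0),
        seed=seed,
        **kwargs,
    )


def test_error_free_channel_copies_gold():
    cohort = simulate_cohort(single_indicator_config(p=0.4, seed=3))
    gold = cohort[cohort["source"] == "gold"].set_index("observation_id")["ind"]
    exit_ = cohort[cohort["source"] == "exit"].set_index("observation_id")["ind"]
    assert gold.sort_index().equals(exit_.sort_index())


def test_zero_prevalence_only_false_positives():
    cohort = simulate_cohort(single_indicator_config(p=0.0, se=0.8, sp=0.7, seed=5))
    gold = cohort.loc[cohort["source"] == "gold", "ind"]
    assert set(gold) == {"0"}
    exit_ = cohort.loc[cohort["source"] == "exit", "ind"]
    # positives arise only through 1 - Sp
    rate = (exit_ == "1").mean()
    assert rate == pytest.approx(0.3, abs=0.03)


def test_empirical_error_rates_recover_configured_values():
    """Large-n tabulation of simulated truth vs report (law of large numbers)."""
    config = single_indicator_config(p=0.5, se=0.8, sp=0.9, births=2000, seed=17)
    cohort = simulate_cohort(config)  # 10 facilities x 2000 births = 20000
    t = build_two_by_two(link_pairs(cohort, "ind", "exit"))
    se_hat = t.a / (t.a + t.c)
    sp_hat = t.d / (t.b + t.d)
    assert se_hat == pytest.approx(0.8, abs=0.01)
    assert sp_hat == pytest.approx(0.9, abs=0.01)


def test_dk_and_missing_fractions_match_configured_rates():
    config = single_indicator_config(
        p=0.5, se=0.9, sp=0.9, dk=0.10, miss=0.05, births=2000, seed=23
    )
    cohort = simulate_cohort(config)
    exit_ = cohort.loc[cohort["source"] == "exit", "ind"]
    assert (exit_ == "DK").mean() == pytest.approx(0.10, abs=0.01)
    assert (exit_ == "NA").mean() == pytest.approx(0.05, abs=0.01)


def test_dk_plus_missing_over_one_rejected():
    with pytest.raises(ConfigurationError):
        MethodErrorProfile(0.9, 0.9, dont_know_rate=0.6, missing_rate=0.5)


def test_identical_seed_and_config_byte_identical():
    config = single_indicator_config(p=0.3, se=0.9, sp=0.8, dk=0.02, seed=99)
    buffers = []
    for _ in range(2):
        buf = io.StringIO()
        write_cohort(simulate_cohort(config), buf)
        buffers.append(buf.getvalue())
    assert buffers[0] == buffers[1]


def test_different_seeds_differ():
    a = simulate_cohort(single_indicator_config(p=0.5, seed=1))
    b = simulate_cohort(single_indicator_config(p=0.5, seed=2))
    assert not a.equals(b)


def test_facility_clustering_increases_with_effect_sd():
    """Between-facility variance of gold prevalence grows with the random
    effect; with sd=0 it matches binomial sampling noise."""

    def facility_variance(sd, seed):
        config = single_indicator_config(
            p=0.5, births=500, facility_effect_sd=sd, seed=seed
        )
        cohort = simulate_cohort(config)
        gold = cohort[cohort["source"] == "gold"]
        prev = gold.groupby("facility_id")["ind"].apply(lambda s: (s == "1").mean())
        return prev.var()

    v0 = facility_variance(0.0, 31)
    v1 = facility_variance(1.0, 31)
    v2 = facility_variance(2.0, 31)
    assert v0 < 0.002  # ~ binomial noise 0.25/500 = 5e-4
    assert v0 < v1 < v2


class TestFollowupSubsample:
    def _config(self, n_per_round, births=60, seed=0):
        return SyntheticCohortConfig(
            indicators={
                "ind": IndicatorModel(0.5, {"followup": MethodErrorProfile()})
            },
            rounds=("R1", "R2", "R3", "R4", "R5"),
            followup_rounds=("R1", "R2", "R3"),
            followup_per_round=n_per_round,
            births_per_facility_round=births,
            facility_effect_sd=0.0,
            seed=seed,
        )

    def test_counts_per_selected_round(self):
        cohort = simulate_cohort(self._config(150))
        fu = cohort[cohort["source"] == "followup"]
        counts = fu.groupby("round_id").size()
        assert set(counts.index) == {"R1", "R2", "R3"}
        assert (counts == 150).all()  # ~600 births available per round

    def test_zero_keeps_nothing(self):
        cohort = simulate_cohort(self._config(0))
        assert (cohort["source"] == "followup").sum() == 0

    def test_none_keeps_all_in_selected_rounds(self):
        cohort = simulate_cohort(self._config(None))
        fu = cohort[cohort["source"] == "followup"]
        births = cohort[cohort["source"] == "gold"]
        in_rounds = births["round_id"].isin(("R1", "R2", "R3")).sum()
        assert len(fu) == in_rounds

    def test_sampling_reproducible_under_seed(self):
        a = simulate_cohort(self._config(50, seed=4))
        b = simulate_cohort(self._config(50, seed=4))
        ids = lambda c: list(c.loc[c["source"] == "followup", "observation_id"])
        assert ids(a) == ids(b)

    def test_shortfall_takes_available(self):
        cohort = simulate_cohort(self._config(10_000))
        fu = cohort[cohort["source"] == "followup"]
        gold = cohort[cohort["source"] == "gold"]
        for r in ("R1", "R2", "R3"):
            assert (fu["round_id"] == r).sum() == (gold["round_id"] == r).sum()

    def test_missing_round_warns(self):
        cohort = simulate_cohort(self._config(5))
        with pytest.warns(UserWarning, match="R9"):
            subsample_followup(cohort, ["R9"], 5)


def test_reference_config_matches_study_shape(reference):
    config = SyntheticCohortConfig.from_reference(seed=0)
    assert config.n_facilities == 10
    assert len(config.rounds) == 5
    assert len(config.indicators) == 25
    n_profiles = sum(len(m.profiles) for m in config.indicators.values())
    assert n_profiles == int(reference["auc"].notna().sum())  # printed rows only
    cohort = simulate_cohort(config)
    births = cohort.loc[cohort["source"] == "gold", "observation_id"].nunique()
    assert births == pytest.approx(1889, rel=0.10)
    assert (cohort["source"] == "followup").sum() == 450
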