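"""Synthetic multi-facility, multi-round matched-pair cohorts.

Generates the measurement structure the validation analysis consumes: for
each birth, a gold-standard (observation) record plus one record per
comparison method (exit interview, follow-up interview, maternity register),
each reporting every binary indicator through an error channel with
configurable sensitivity, specificity, don't-know rate and missingness.

Generative model, per indicator:

* facility effect ``u_f ~ Normal(0, facility_effect_sd)`` drawn once per
  facility (logit scale), so prevalence clusters within facility;
* true status ``~ Bernoulli(expit(logit(p) + u_f))``;
* a method's report equals the true status with probability Se (when truly
  positive) or reports negative with probability Sp (when truly negative);
* the report is then overwritten with don't-know or missing at the
  configured rates, independently of true status by default
  (non-differential); a differential switch restricts don't-know responses
  to truly-negative births;
* gold records are never don't-know (observers record what they see);
  absence on the gold side is missing.

Defaults mirror the Gombe study conditions: 10 facilities, 5 data-collection
rounds, a mean of 37.8 births per facility-round (~1889 births in total),
and household follow-up for a simple random sample of 150 births from each
of the first three rounds.  ``SyntheticCohortConfig.from_reference()``
additionally loads per-indicator prevalences and per-method error profiles
from the published estimates table.

One global integer seed governs all draws through a documented
stream-splitting scheme (one child stream per facility, spawned in facility
order, plus one stream for follow-up subsampling), so regeneration is
byte-identical for a given config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from covval.catalogue import METHODS, SOURCES
from covval.errors import ConfigurationError
from covval.reference import load_reference_estimates

__all__ = [
    "MethodErrorProfile",
    "IndicatorModel",
    "SyntheticCohortConfig",
    "simulate_cohort",
    "subsample_followup",
    "read_cohort",
    "write_cohort",
]

#: Stable source ordering for output rows.
_SOURCE_ORDER = {s: i for i, s in enumerate(SOURCES)}


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class MethodErrorProfile:
    """Error channel of one recording method for one indicator."""

    sensitivity: float = 1.0
    specificity: float = 1.0
    dont_know_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "dont_know_rate", "missing_rate"):
            _check_proportion(name, getattr(self, name))
        if self.dont_know_rate + self.missing_rate > 1.0:
            raise ConfigurationError(
                "dont_know_rate + missing_rate must not exceed 1, got "
                f"{self.dont_know_rate} + {self.missing_rate}"
            )


@dataclass(frozen=True)
class IndicatorModel:
    """Gold prevalence plus per-method error profiles for one indicator."""

    prevalence: float
    profiles: Mapping[str, MethodErrorProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_proportion("prevalence", self.prevalence)
        unknown = set(self.profiles) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods in profiles: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the generative model (defaults = study conditions)."""

    indicators: Mapping[str, IndicatorModel]
    n_facilities: int = 10
    rounds: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")
    births_per_facility_round: float = 37.8
    facility_effect_sd: float = 0.6
    followup_rounds: tuple[str, ...] | None = None  # default: first 3 rounds
    followup_per_round: int | None = 150
    gold_missing_rate: float = 0.0
    differential_dk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.indicators:
            raise ConfigurationError("config needs at least one indicator")
        if self.n_facilities < 1:
            raise ConfigurationError("n_facilities must be >= 1")
        if self.births_per_facility_round <= 0:
            raise ConfigurationError("births_per_facility_round must be > 0")
        if self.facility_effect_sd < 0:
            raise ConfigurationError("facility_effect_sd must be >= 0")
        _check_proportion("gold_missing_rate", self.gold_missing_rate)
        if self.followup_rounds is None:
            object.__setattr__(self, "followup_rounds", tuple(self.rounds[:3]))
        unknown = set(self.followup_rounds) - set(self.rounds)
        if unknown:
            raise ConfigurationError(f"followup_rounds not in rounds: {sorted(unknown)}")

    @property
    def methods_present(self) -> tuple[str, ...]:
        present = set()
        for model in self.indicators.values():
            present |= set(model.profiles)
        return tuple(m for m in METHODS if m in present)

    @classmethod
    def from_reference(
        cls,
        *,
        seed: int = 0,
        scale: float = 1.0,
        facility_effect_sd: float = 0.6,
        followup_per_round: int | None = 150,
        dont_know: bool = True,
    ) -> "SyntheticCohortConfig":
        """Config emulating the published study conditions.

        Loads each indicator's gold prevalence and, for every
        indicator-method row whose sensitivity/specificity the study
        reported, an error profile with those rates.  Rows the study left
        without metrics have no published error channel to emulate and are
        not simulated.  ``scale`` multiplies the births per facility-round
        (``scale=1`` gives ~1889 births); ``followup_per_round=None`` keeps
        follow-up records for every birth.  A published don't-know rate of
        exactly 5% is simulated as 4.7%: a rate that both rounds to 5 and
        passed the study's >5% exclusion gate must lie in (4.5, 5.0], and
        4.7 is interior to that interval.
        """
        ref = load_reference_estimates()
        indicators: dict[str, IndicatorModel] = {}
        for indicator_id, rows in ref.groupby("indicator_id", sort=False):
            prev = float(rows.iloc[0]["gold_prevalence_pct"]) / 100.0
            profiles = {}
            for row in rows.itertuples(index=False):
                if pd.isna(row.sensitivity_pct) or pd.isna(row.specificity_pct):
                    continue
                dk_pct = float(row.dont_know_pct)
                dk = (4.7 if dk_pct == 5 else dk_pct) / 100.0 if dont_know else 0.0
                profiles[row.method] = MethodErrorProfile(
                    sensitivity=float(row.sensitivity_pct) / 100.0,
                    specificity=float(row.specificity_pct) / 100.0,
                    dont_know_rate=dk,
                    missing_rate=0.0,
                )
            indicators[indicator_id] = IndicatorModel(prev, profiles)
        return cls(
            indicators=indicators,
            births_per_facility_round=37.8 * scale,
            facility_effect_sd=facility_effect_sd,
            followup_per_round=followup_per_round,
            seed=seed,
        )


def _report_channel(
    rng: np.random.Generator,
    truth: np.ndarray,
    profile: MethodErrorProfile,
    differential_dk: bool,
) -> np.ndarray:
    """Push true binary status through one method's error channel.

    Returns an integer code array: 1 positive, 0 negative, 2 don't-know,
    3 missing.
    """
    n = truth.shape[0]
    u = rng.random(n)
    report = np.where(truth == 1, (u < profile.sensitivity).astype(np.int8),
                      (u >= profile.specificity).astype(np.int8))
    v = rng.random(n)
    dk = v < profile.dont_know_rate
    if differential_dk:
        dk &= truth == 0
    miss = (~dk) & (v < profile.dont_know_rate + profile.missing_rate)
    report = report.astype(np.int8)
    report[dk] = 2
    report[miss] = 3
    return report


_CODES = np.array(["0", "1", "DK", "NA"], dtype=object)


def simulate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Simulate a cohort under ``config``.

    Returns a long-format DataFrame with one row per (birth, source):
    columns ``observation_id, facility_id, round_id, source`` followed by
    one column per indicator holding codes ``"1"/"0"/"DK"/"NA"``.
    Identical seed and config give byte-identical output.
    """
    indicator_ids = list(config.indicators)
    methods = config.methods_present
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_facilities + 1)
    followup_ss = children[-1]

    frames: list[pd.DataFrame] = []
    for f in range(config.n_facilities):
        rng = np.random.default_rng(children[f])
        facility_id = f"F{f + 1:02d}"
        # one facility effect per indicator, drawn before any round
        u_f = rng.normal(0.0, config.facility_effect_sd, size=len(indicator_ids))
        for round_id in config.rounds:
            n_births = int(rng.poisson(config.births_per_facility_round))
            if n_births == 0:
                continue
            obs_ids = [f"{facility_id}-{round_id}-{k + 1:04d}" for k in range(n_births)]
            # codes per source: dict source -> (n_births x n_ind) int codes
            codes: dict[str, np.ndarray] = {
                s: np.full((n_births, len(indicator_ids)), 3, dtype=np.int8)
                for s in ("gold", *methods)
            }
            for j, ind in enumerate(indicator_ids):
                model = config.indicators[ind]
                p = model.prevalence
                if 0.0 < p < 1.0:
                    p = float(expit(logit(p) + u_f[j]))
                truth = (rng.random(n_births) < p).astype(np.int8)
                gold = truth.copy()
                if config.gold_missing_rate > 0:
                    gold_miss = rng.random(n_births) < config.gold_missing_rate
                    gold[gold_miss] = 3
                codes["gold"][:, j] = gold
                for m in methods:
                    profile = model.profiles.get(m)
                    if profile is None:
                        continue  # method does not assess this indicator
                    codes[m][:, j] = _report_channel(
                        rng, truth, profile, config.differential_dk
                    )
            for source in ("gold", *methods):
                block = pd.DataFrame(
                    _CODES[codes[source]], columns=indicator_ids, dtype=object
                )
                block.insert(0, "observation_id", obs_ids)
                block.insert(1, "facility_id", facility_id)
                block.insert(2, "round_id", round_id)
                block.insert(3, "source", source)
                frames.append(block)

    if not frames:
        cols = ["observation_id", "facility_id", "round_id", "source", *indicator_ids]
        return pd.DataFrame(columns=cols)
    cohort = pd.concat(frames, ignore_index=True)
    cohort = _sort_cohort(cohort)
    if "followup" in methods:
        cohort = subsample_followup(
            cohort,
            config.followup_rounds,
            config.followup_per_round,
            seed=followup_ss,
        )
    return cohort


def _sort_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    key = cohort["source"].map(_SOURCE_ORDER)
    order = (
        cohort.assign(_k=key)
        .sort_values(["facility_id", "round_id", "observation_id", "_k"], kind="stable")
        .index
    )
    return cohort.loc[order].reset_index(drop=True)


def subsample_followup(
    cohort: pd.DataFrame,
    rounds_selected: Sequence[str],
    n_per_round: int | None,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Retain follow-up rows for a simple random sample of births.

    Keeps ``min(n_per_round, available)`` follow-up rows per selected round,
    sampled without replacement from the round's observed births; follow-up
    rows outside the selected rounds are dropped.  ``n_per_round=None``
    keeps every follow-up row in the selected rounds.  Sampling is
    reproducible under ``seed``.
    """
    followup = cohort["source"] == "followup"
    if not followup.any():
        return cohort
    present_rounds = set(cohort["round_id"].unique())
    rng = np.random.default_rng(seed)
    keep_ids: list[str] = []
    for round_id in rounds_selected:
        if round_id not in present_rounds:
            warnings.warn(f"round {round_id!r} has no births; zero follow-up rows")
            continue
        in_round = cohort.loc[followup & (cohort["round_id"] == round_id)]
        ids = in_round["observation_id"].to_numpy()
        if n_per_round is None or len(ids) <= n_per_round:
            keep_ids.extend(ids)
        else:
            keep_ids.extend(rng.choice(ids, size=n_per_round, replace=False))
    keep = set(keep_ids)
    drop = followup & ~cohort["observation_id"].isin(keep)
    return cohort.loc[~drop].reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV with stable column order and codes."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, keeping indicator codes as strings."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.replace({"": "NA"})
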