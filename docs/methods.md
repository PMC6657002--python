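# Methods

## The validation model

Each childbirth-care indicator is a binary event per birth. Direct birth
observation is treated as error-free truth (the gold standard); each
comparison recording method — facility exit interview, household follow-up
interview, facility maternity register — is a noisy binary channel
characterised by its sensitivity Se (probability of reporting an event that
occurred) and specificity Sp (probability of reporting no event when none
occurred). Linking on a unique observation ID yields matched pairs, and a
2×2 table per indicator–method pair.

Individual-level accuracy is summarised by Se, Sp and the area under the
ROC curve; for one binary test the ROC polygon has a single interior vertex
and AUC = (Se + Sp)/2, so 0.5 is a random guess and 1 complete accuracy.
Population-level bias is summarised by the inflation factor

    IF = P_est / P,    P_est = P·Se + (1 − P)(1 − Sp),

the ratio of the prevalence a survey relying on the comparison method would
estimate to the gold-standard prevalence P. IF is driven by the false
positive mass (1 − P)(1 − Sp) relative to P: indicators with high prevalence
and mediocre specificity can have IF ≈ 1 (low population bias) while being
individually inaccurate, and rare indicators amplify even small specificity
deficits into large IF — which is why both criteria are required for "high
overall validity": AUC ≥ 0.70 (inclusive) and 0.75 < IF < 1.25 (strict on
both sides).

Assumptions worth keeping in mind: the gold standard is assumed error-free
(observer error, Hawthorne effects are outside the model); misclassification
is assumed non-differential with respect to everything except true status;
and DK/missing exclusion assumes exclusions are ignorable for Se/Sp — the
DK-rate eligibility gate (≤5% of comparison responses) bounds how much this
assumption is leaned on.

## Eligibility and exclusion rules

Pairs are dropped from the 2×2 cells, and tallied, when: the gold value is
missing (truth unclassifiable), the comparison value is missing, or the
comparison value is an explicit "don't know". The DK rate is computed over
comparison *responses* (missing is not a response); the gold standard has no
DK state by construction. Metrics are computed only when every cell holds at
least 5 observations and the DK rate is ≤5%; both gates are always evaluated
so a report can show which failed. Conservation (cells + exclusions = pairs)
is asserted property-style in the test suite.

## Clustered prevalence intervals

Care practices cluster strongly within facility, so the prevalence CI uses a
logit-scale Wald interval with a cluster-robust (sandwich) variance over
facilities (statsmodels GLM, intercept-only binomial fit). Unclustered
proportions — Se, Sp, prevalence in a single cluster, or degenerate
estimates of 0 or 1 — use the exact Clopper–Pearson interval (Wilson is
available behind a flag). The AUC interval is a Wald combination,
var(AUC) = [var(Se) + var(Sp)]/4 with binomial variances and normal
quantiles, truncated to [0, 1]; this is an approximation chosen for
transparency, and no claim is made that it reproduces any published AUC
interval endpoints.

## Classification and rounding

Classification uses full-precision AUC and IF against the cutoffs; rounding
is a display concern. Report formatting mirrors validation-table convention:
whole percents for prevalence, agreement, Se and Sp; two decimals for AUC
and IF; rounding is half-away-from-zero (not banker's). Cross-checks against
published values use ±0.01 for AUC because published values were rounded
from unrounded intermediates. The same check is *not* attainable for IF at
low prevalence: IF recomputed from whole-percent inputs differs from the
published value by up to ~0.25 when P ≤ 12% because the (1 − P)/P factor
multiplies the rounding error in 1 − Sp (a specificity printed as 100% at 3%
prevalence contributes anywhere from 0 to ~0.17 of IF). The test suite keeps
this blanket check and documents its failure rather than widening the
tolerance; the moderate-to-high-prevalence worked-example rows reproduce
exactly.

Degenerate inputs are flagged, not coerced: Se is undefined without
gold-positive pairs, Sp without gold-negatives, IF at P = 0 (undefined, not
infinite), agreement on an empty table; each carries a reason code through
the report.

## Indicator derivations

Threshold rules follow standard survey definitions: adolescent birth is age
< 20 at delivery (the DHS adolescent-birth convention, consistent with
15–19 age banding); grand multipara is prior parity ≥ 4 (inclusive); low
birthweight is strictly < 2500 g, so 2500 g exactly is not LBW. Skilled
attendance maps provider cadre ∈ {doctor, nurse, midwife} to positive;
community health extension workers, hospital assistants, other staff and
traditional birth attendants are negative, with a configuration hook for
extra local cadres. Raw values outside plausibility ranges (age 10–60 y,
birthweight 500–6000 g, parity ≥ 0) raise errors naming the observation.

The essential-newborn-care composite is the conjunction of immediate
breastfeeding initiation and the newborn being kept warm, with a source
dialect: maternity registers record the practices within 30 minutes of
birth, observation and interviews within the first hour. The composite
truth table is symmetric with dominance negative > don't-know > missing: a
definitively absent component makes the composite definitively negative;
among non-negative states an explicit DK outranks mere absence (a
respondent who says "don't know" to one component has answered). Which gold
field operationalises "kept warm" (skin-to-skin placement vs drying and
wrapping) is a study-level choice, so the component field names are
configurable.

## The synthetic cohort

The generator emulates the measurement structure the analysis consumes, with
defaults set to the study conditions: 10 facilities × 5 rounds, Poisson
births with mean 37.8 per facility-round (~1889 total), follow-up as a
simple random sample of 150 births from each of the first three rounds.
Per indicator: a facility random intercept u_f ~ N(0, σ) on the logit of
prevalence (σ default 0.6, a moderate between-facility spread typical of
care-practice indicators and sufficient to widen prevalence CIs well beyond
binomial); true status Bernoulli(expit(logit p + u_f)); each method's report
passes through its Se/Sp channel and is then overwritten by DK/missing at
configured rates, non-differential by default (a differential switch
restricts DK to true negatives). Clustering enters through prevalence only,
not through error rates — the simplest mechanism that reproduces wide
cluster-adjusted prevalence intervals — with per-method profiles left as the
hook if per-facility error rates are ever needed. One integer seed drives
everything through per-facility spawned substreams plus one subsampling
stream, so output is byte-identical per (config, seed).

`SyntheticCohortConfig.from_reference()` loads prevalences and per-method
Se/Sp/DK from the shipped published-estimates table. Rows the study left
without metrics have no published channel to emulate and are not simulated.
A published DK of exactly 5% is simulated as 4.7%: a rate that both rounds
to 5 and passed the >5% gate must lie in (4.5, 5.0], and an interior value
avoids parking the simulation on the eligibility boundary.

What the generator does not emulate: correlation between indicators within
a birth, differential misclassification by facility or by covariates,
recall decay as a function of time (follow-up error rates are simply the
published ones), observer error in the gold standard, and non-random
follow-up loss. Passing tests therefore demonstrate that the analysis
machinery is correct under the stated error model, not that any particular
real-world data source is valid.

## Poolability screen

Marginal homogeneity across data-collection rounds is tested per
indicator–method with a cluster-adjusted McNemar statistic, clusters =
rounds (facility×round or any column is configurable):
T = [Σ(bₖ−cₖ)]² / Σ(bₖ−cₖ)², referred to χ²₁. This form needs only
per-cluster discordant counts and reduces exactly to the classical McNemar
(b−c)²/(b+c) for singleton clusters; under cluster replication it is
deliberately not invariant (numerator ×4, denominator ×2). The variant name
is recorded in output metadata. Degenerate data (no discordant pairs) yield
statistic 0, p = 1, flagged; a single cluster is an error advising the
plain McNemar test. No multiplicity correction is applied across screens;
instead the overall recommendation is "combine" when the number of flags
does not exceed the chance allowance ⌈α·n_screens⌉, else "review" — flags
are reported, never dropped.

A property of this variance family worth knowing: it has high power against
a *consistent* marginal shift across clusters, but little power against a
shift confined to a single cluster, because that cluster inflates the
between-cluster variance estimate as much as the mean difference (the
statistic is bounded by the number of clusters). Both behaviours are frozen
in the test suite via seeded Monte-Carlo, along with a type-I error check
(empirical rejection 0.048 at α = 0.05 under a marginally homogeneous
null).

## Sample size

The precision-based (normal-approximation) formula gives
n_pos = ⌈z²·Se(1−Se)/d²⌉ = 189 and n_neg = 165 at the default planning
settings (prevalence 0.5, Se 60% ± 7%, Sp 70% ± 7%, α = 0.05), hence a
total of 378 after prevalence inflation. Published planning figures for
such designs are sometimes larger round numbers; this module reports what
the formula yields and leaves any inflation for design effects or
nonresponse to the caller.

## Problem sizes in the test suite

Stochastic checks are sized to be decisive yet quick: parameter recovery
uses 100 replicates of ~20,000 matched pairs (Clopper–Pearson coverage of
the generating Se and Sp, ≥90% required per metric); the type-I error check
uses 2,000 replicates of 10 clusters × 200 pairs; the end-to-end
classification check simulates ~19,000 births under the published error
profiles and compares pipeline classification to the classification of the
generating parameters for rows whose parameters sit at least a few
Monte-Carlo standard errors from the decision boundaries (margins: 0.02 in
AUC, 0.05 in IF, 20 expected observations per cell) — rows closer than
that are genuinely undecidable at finite n and are skipped rather than
asserted flakily.

## Known limitations

* The AUC interval method is an approximation; published interval endpoints
  are not reproducible without unrounded cell counts.
* IF cross-checks from whole-percent inputs are unreliable below ~15%
  prevalence (see rounding section).
* The clustered prevalence interval relies on an asymptotic sandwich
  variance over 10 facilities; with few clusters it can undercover.
* The poolability screen's power profile (above) means a round-specific
  reporting shift can pass the screen undetected.
* Validity metrics are computed for binary indicators only; ordinal or
  continuous agreement (e.g. birthweight in grams) is out of scope.
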