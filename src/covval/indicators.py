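"""Derive binary indicator values from raw per-birth fields.

Every indicator value is tri-state-plus-one: positive, negative, an explicit
"don't know" response, or missing.  Gold-standard (birth observation) records
never carry "don't know" — observers record what they see, so absence is
missing, not DK.

Derivation rules
----------------
identity
    The raw field already holds a coded binary response; DK/missing pass
    through unchanged.
threshold_lt / threshold_ge
    Numeric cut points on raw fields, e.g. adolescent birth (age < 20 at
    delivery), grand multipara (prior parity >= 4), low birthweight
    (< 2500 g, strict — 2500 g exactly is not LBW).
cadre_map
    Skilled attendance: positive iff the provider cadre is doctor, nurse or
    midwife.  Community health extension workers, hospital assistants, other
    facility staff and traditional birth attendants map to negative, as does
    any caller-supplied extra local cadre.
composite
    Essential newborn care: immediate initiation of breastfeeding AND the
    baby kept warm, within a time window that differs by source dialect —
    maternity registers record the practices within 30 minutes of birth,
    while observations (and interview recall) use the first hour.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Mapping

from covval.catalogue import IndicatorDefinition
from covval.errors import ConfigurationError, DataError

__all__ = [
    "TriState",
    "SKILLED_CADRES",
    "KNOWN_CADRES",
    "derive_binary",
    "derive_essential_newborn_care",
    "to_tristate",
]


class TriState(str, Enum):
    """Indicator value: positive / negative / explicit don't-know / missing.

    The string values double as the stable CSV codes.
    """

    POSITIVE = "1"
    NEGATIVE = "0"
    DONT_KNOW = "DK"
    MISSING = "NA"

    def __repr__(self) -> str:  # terse in test output
        return f"TriState.{self.name}"


#: Provider cadres counted as skilled birth attendants.
SKILLED_CADRES: frozenset[str] = frozenset({"doctor", "nurse", "midwife"})

#: Recognized provider cadre vocabulary (unskilled cadres map to negative).
KNOWN_CADRES: frozenset[str] = SKILLED_CADRES | frozenset(
    {
        "chew",
        "community_health_extension_worker",
        "junior_chew",
        "hospital_assistant",
        "other_facility_staff",
        "other_non_staff",
        "traditional_birth_attendant",
    }
)

#: Plausibility ranges for raw numeric fields.
FIELD_RANGES: dict[str, tuple[float, float]] = {
    "age_years": (10.0, 60.0),
    "birthweight_g": (500.0, 6000.0),
    "parity": (0.0, math.inf),
}

_CODE_MAP = {
    "1": TriState.POSITIVE,
    "0": TriState.NEGATIVE,
    "DK": TriState.DONT_KNOW,
    "NA": TriState.MISSING,
    "dk": TriState.DONT_KNOW,
    "na": TriState.MISSING,
    "": TriState.MISSING,
}


def to_tristate(value: object) -> TriState:
    """Coerce a raw coded value (1/0/"DK"/"NA"/None/NaN/bool) to a TriState."""
    if isinstance(value, TriState):
        return value
    if value is None:
        return TriState.MISSING
    if isinstance(value, bool):
        return TriState.POSITIVE if value else TriState.NEGATIVE
    if isinstance(value, (int, float)):
        if isinstance(value, float) and math.isnan(value):
            return TriState.MISSING
        if value in (0, 1):
            return TriState(str(int(value)))
        raise DataError(f"cannot interpret {value!r} as a binary indicator code")
    if isinstance(value, str):
        key = value.strip()
        if key in _CODE_MAP:
            return _CODE_MAP[key]
        try:
            num = float(key)
        except ValueError:
            raise DataError(f"cannot interpret {value!r} as a binary indicator code")
        return to_tristate(num)
    raise DataError(f"cannot interpret {value!r} as a binary indicator code")


def _numeric_or_state(record: Mapping, field: str) -> float | TriState:
    """Fetch a numeric raw field; DK/missing codes become their TriState."""
    value = record.get(field)
    if value is None:
        return TriState.MISSING
    if isinstance(value, str):
        key = value.strip()
        if key in _CODE_MAP and _CODE_MAP[key] in (TriState.DONT_KNOW, TriState.MISSING):
            return _CODE_MAP[key]
        try:
            value = float(key)
        except ValueError:
            raise DataError(
                f"observation {record.get('observation_id')!r}: "
                f"non-numeric value {value!r} in field {field!r}"
            )
    if isinstance(value, float) and math.isnan(value):
        return TriState.MISSING
    num = float(value)
    lo, hi = FIELD_RANGES.get(field, (-math.inf, math.inf))
    if not lo <= num <= hi:
        raise DataError(
            f"observation {record.get('observation_id')!r}: {field}={num} "
            f"outside plausible range [{lo}, {hi}]"
        )
    return num


def _normalise_cadre(raw: str) -> str:
    return raw.strip().lower().replace(" ", "_").replace("-", "_")


def derive_binary(
    record: Mapping,
    definition: IndicatorDefinition,
    *,
    extra_cadres: Iterable[str] = (),
) -> TriState:
    """Derive one indicator's tri-state value from a raw birth record.

    ``record`` is any mapping of raw field names to values (a dict, or a
    pandas Series from a cohort row).  ``extra_cadres`` extends the cadre
    vocabulary with local categories that map to negative.

    Deterministic and total over in-range inputs; raw values outside the
    plausibility ranges raise :class:`~covval.errors.DataError` naming the
    observation.
    """
    rule = definition.derivation
    if rule == "identity":
        return to_tristate(record.get(definition.source_field))
    if rule in ("threshold_lt", "threshold_ge"):
        value = _numeric_or_state(record, definition.source_field)
        if isinstance(value, TriState):
            return value
        if rule == "threshold_lt":
            return TriState.POSITIVE if value < definition.threshold else TriState.NEGATIVE
        return TriState.POSITIVE if value >= definition.threshold else TriState.NEGATIVE
    if rule == "cadre_map":
        raw = record.get(definition.source_field)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return TriState.MISSING
        if isinstance(raw, str) and raw.strip() in _CODE_MAP:
            state = _CODE_MAP[raw.strip()]
            if state in (TriState.DONT_KNOW, TriState.MISSING):
                return state
        cadre = _normalise_cadre(str(raw))
        vocabulary = KNOWN_CADRES | {_normalise_cadre(c) for c in extra_cadres}
        if cadre not in vocabulary:
            raise DataError(
                f"observation {record.get('observation_id')!r}: "
                f"unknown provider cadre {raw!r}"
            )
        return TriState.POSITIVE if cadre in SKILLED_CADRES else TriState.NEGATIVE
    if rule == "composite":
        dialect = (
            "register-30min" if record.get("source") == "register" else "gold-60min"
        )
        components = tuple(f.strip() for f in definition.source_field.split(","))
        return derive_essential_newborn_care(record, dialect, components=components)
    raise ConfigurationError(f"unknown derivation rule {rule!r}")


def derive_essential_newborn_care(
    record: Mapping,
    source_dialect: str,
    *,
    components: tuple[str, str] = ("immediate_breastfeeding", "kept_warm"),
) -> TriState:
    """Essential-newborn-care composite: breastfeeding AND kept warm.

    ``source_dialect`` selects the time window the component flags refer to:
    ``"gold-60min"`` reads the components as named (within the first hour,
    the globally-defined window used by observers and interviews);
    ``"register-30min"`` reads the maternity register's 30-minute variants
    (component field name + ``"_30m"``, falling back to the plain name when
    no 30-minute field is present).

    Truth table (symmetric in the two components): negative if either
    component is negative; else don't-know if either is DK; else missing if
    either is missing; else positive.  A definitively absent component makes
    the composite definitively negative regardless of the other component's
    state.
    """
    if source_dialect == "gold-60min":
        fields = components
    elif source_dialect == "register-30min":
        fields = tuple(
            f"{c}_30m" if f"{c}_30m" in record else c for c in components
        )
    else:
        raise ConfigurationError(
            f"unknown essential-newborn-care dialect {source_dialect!r} "
            "(expected 'gold-60min' or 'register-30min')"
        )
    states = [to_tristate(record.get(f)) for f in fields]
    if TriState.NEGATIVE in states:
        return TriState.NEGATIVE
    if TriState.DONT_KNOW in states:
        return TriState.DONT_KNOW
    if TriState.MISSING in states:
        return TriState.MISSING
    return TriState.POSITIVE
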