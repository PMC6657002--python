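"""Indicator catalogue: which childbirth-care indicators exist, how each is
derived from raw per-birth fields, and which data recording methods assess it.

The shipped default catalogue covers the 25 indicators of the Gombe State
childbirth-care validation study: 20 assessed by facility exit interview, 15
by household follow-up interview, and 10 by the facility maternity register,
grouped into skilled attendance & companionship, care for the woman
(background, respectful care, clinical care) and care for the newborn
(immediate postnatal care, outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from covval.errors import ConfigurationError

#: Comparison data recording methods, in presentation order.
METHODS: tuple[str, ...] = ("exit", "followup", "register")

#: All record sources: the gold standard plus the comparison methods.
SOURCES: tuple[str, ...] = ("gold",) + METHODS

#: Recognized derivation rules for turning raw fields into binary indicators.
DERIVATIONS: tuple[str, ...] = (
    "identity",
    "threshold_lt",
    "threshold_ge",
    "cadre_map",
    "composite",
)


@dataclass(frozen=True)
class IndicatorDefinition:
    """One catalogue row: an indicator and how to assess it.

    Parameters
    ----------
    indicator_id : str
        Short stable token, unique within a catalogue.
    label : str
        Human-readable name.
    group : str
        Indicator family (e.g. ``"care for the newborn - immediate postnatal"``).
    methods_assessed : frozenset of str
        Non-empty subset of :data:`METHODS`.
    derivation : str
        One of :data:`DERIVATIONS`; how raw fields map to the binary value.
    source_field : str
        Raw field consumed by the derivation (comma-separated pair for
        composites).
    threshold : float or None
        Cut point for threshold rules (strict ``<`` for ``threshold_lt``,
        inclusive ``>=`` for ``threshold_ge``).
    positive_meaning : str
        What a positive value asserts about the birth.
    """

    indicator_id: str
    label: str
    group: str
    methods_assessed: frozenset[str]
    derivation: str
    source_field: str
    threshold: float | None = None
    positive_meaning: str = ""

    def __post_init__(self) -> None:
        if not self.methods_assessed:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: methods_assessed is empty"
            )
        unknown = set(self.methods_assessed) - set(METHODS)
        if unknown:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: unknown methods {sorted(unknown)}"
            )
        if self.derivation not in DERIVATIONS:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: unknown derivation "
                f"{self.derivation!r} (expected one of {DERIVATIONS})"
            )
        if self.derivation in ("threshold_lt", "threshold_ge") and self.threshold is None:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: threshold rule without a threshold"
            )


@dataclass
class Catalogue:
    """An ordered collection of :class:`IndicatorDefinition`."""

    definitions: list[IndicatorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.indicator_id for d in self.definitions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate indicator_id(s): {sorted(dupes)}")
        self._by_id = {d.indicator_id: d for d in self.definitions}

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self) -> Iterator[IndicatorDefinition]:
        return iter(self.definitions)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise KeyError(f"indicator {indicator_id!r} not in catalogue") from None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def for_method(self, method: str) -> "Catalogue":
        """Sub-catalogue of indicators assessed by one recording method."""
        if method not in METHODS:
            raise ConfigurationError(f"unknown method {method!r}")
        return Catalogue([d for d in self.definitions if method in d.methods_assessed])

    def totals(self) -> dict[str, int]:
        """Indicator counts overall and per method (gold assesses all)."""
        out = {"gold": len(self)}
        for m in METHODS:
            out[m] = len(self.for_method(m))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.definitions:
            row = {
                "indicator_id": d.indicator_id,
                "label": d.label,
                "group": d.group,
                "derivation": d.derivation,
                "source_field": d.source_field,
                "threshold": d.threshold,
                "positive_meaning": d.positive_meaning,
            }
            for m in METHODS:
                row[m] = int(m in d.methods_assessed)
            rows.append(row)
        return pd.DataFrame(rows)


def load_catalogue(path: str | Path | pd.DataFrame) -> Catalogue:
    """Load a catalogue from CSV (or an equivalent DataFrame).

    Expected columns: ``indicator_id, label, group, exit, followup, register,
    derivation, source_field, threshold, positive_meaning`` with 0/1 method
    flags.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    required = {"indicator_id", "label", "group", "derivation", "source_field"} | set(
        METHODS
    )
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"catalogue is missing columns: {sorted(missing)}")
    defs = []
    for rec in df.to_dict("records"):
        methods = frozenset(m for m in METHODS if int(rec[m]) == 1)
        thr = rec.get("threshold")
        thr = None if thr is None or pd.isna(thr) else float(thr)
        defs.append(
            IndicatorDefinition(
                indicator_id=str(rec["indicator_id"]),
                label=str(rec["label"]),
                group=str(rec["group"]),
                methods_assessed=methods,
                derivation=str(rec["derivation"]),
                source_field="" if pd.isna(rec["source_field"]) else str(rec["source_field"]),
                threshold=thr,
                positive_meaning=""
                if pd.isna(rec.get("positive_meaning"))
                else str(rec.get("positive_meaning")),
            )
        )
    return Catalogue(defs)


def load_default_catalogue() -> Catalogue:
    """The shipped 25-indicator catalogue (totals 25/20/15/10)."""
    with resources.files("covval.data").joinpath("indicator_catalogue.csv").open(
        "rb"
    ) as fh:
        return load_catalogue(pd.read_csv(fh))
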