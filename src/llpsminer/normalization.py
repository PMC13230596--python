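"""Rule-based standardization of extracted experimental values.

Model output arrives as free text ("RT", "5 mM", "pH 7.4", "droplet
formation").  Before any record can be scored against a curated label it is
normalized onto canonical scales: temperatures to °C (with room-temperature
aliases collapsed to 25 °C), molar concentrations to µM, protein names
casefolded and resolved through a synonym map, and phase descriptions to a
strict binary.  Units that cannot be converted to a molar scale without
molecular weight (mg/mL and friends) are passed through unchanged and
flagged non-convertible.

All behaviour is driven by a :class:`NormalizationRules` table, loadable
from YAML/JSON; a default table ships with the package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .records import (
    CANONICAL_MOLAR_UNIT,
    CANONICAL_TEMP_UNIT,
    ExperimentRecord,
    Quantity,
)

__all__ = [
    "NormalizationError",
    "NormalizationRules",
    "default_rules",
    "load_rules",
    "normalize_temperature",
    "normalize_concentration",
    "normalize_ph",
    "normalize_phase",
    "canonicalize_protein_name",
    "normalize_record",
]


class NormalizationError(ValueError):
    """A raw value could not be normalized; carries the offending text."""

    def __init__(self, message: str, raw: str):
        super().__init__(message)
        self.raw = raw


def _fold(text: str) -> str:
    """Casefold and collapse internal whitespace."""
    return " ".join(text.casefold().split())


@dataclass(frozen=True)
class NormalizationRules:
    """Lookup tables driving normalization; all alias keys are casefolded."""

    temperature_aliases: Mapping[str, float]
    molar_unit_factors: Mapping[str, float]  # unit -> multiplier to µM
    non_convertible_units: frozenset
    protein_synonyms: Mapping[str, str]
    phase_vocab: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "temperature_aliases",
            {_fold(k): float(v) for k, v in self.temperature_aliases.items()},
        )
        factors = {_fold(k): float(v) for k, v in self.molar_unit_factors.items()}
        if any(f <= 0 for f in factors.values()):
            raise ValueError("molar unit factors must be positive")
        object.__setattr__(self, "molar_unit_factors", factors)
        object.__setattr__(
            self, "non_convertible_units",
            frozenset(_fold(u) for u in self.non_convertible_units),
        )
        syn = {_fold(k): str(v) for k, v in self.protein_synonyms.items()}
        for canon in syn.values():
            # canonical names must be fixed points of the map
            if _fold(canon) in syn and syn[_fold(canon)] != canon:
                raise ValueError(f"synonym map is not idempotent at {canon!r}")
        object.__setattr__(self, "protein_synonyms", syn)
        vocab = {_fold(k): int(v) for k, v in self.phase_vocab.items()}
        if any(v not in (0, 1) for v in vocab.values()):
            raise ValueError("phase vocabulary values must be 0 or 1")
        object.__setattr__(self, "phase_vocab", vocab)

    def with_synonyms(self, synonyms: Mapping[str, str]) -> "NormalizationRules":
        merged = dict(self.protein_synonyms)
        merged.update({_fold(k): v for k, v in synonyms.items()})
        return replace(self, protein_synonyms=merged)


def load_rules(path: Union[str, Path]) -> NormalizationRules:
    """Load a rules table from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return NormalizationRules(
        temperature_aliases=data.get("temperature_aliases", {}),
        molar_unit_factors=data.get("molar_unit_factors", {}),
        non_convertible_units=frozenset(data.get("non_convertible_units", [])),
        protein_synonyms=data.get("protein_synonyms", {}),
        phase_vocab=data.get("phase_vocab", {}),
    )


def default_rules() -> NormalizationRules:
    """The rules table shipped with the package."""
    with resources.as_file(resources.files("llpsminer.data") / "default_rules.yaml") as p:
        return load_rules(p)


# ---------------------------------------------------------------------------
# field normalizers
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"
_TEMP_RE = re.compile(
    rf"^\s*(?P<num>{_NUM})\s*(?:°\s*)?(?P<unit>[cfk])?\s*$", re.IGNORECASE
)
_CONC_RE = re.compile(rf"^\s*(?P<num>{_NUM})\s*(?P<unit>.+?)\s*$")
_PH_RE = re.compile(rf"^\s*(?:ph\s*)?(?P<num>{_NUM})\s*$", re.IGNORECASE)


def normalize_temperature(
    raw: str, rules: Optional[NormalizationRules] = None
) -> Quantity:
    """Normalize a temperature string to a °C quantity.

    Aliases such as "RT" and "room temperature" resolve through the rules
    table (25 °C by default); numeric strings with °C/K/°F suffixes (or bare
    numbers, taken as Celsius) are converted arithmetically.
    """
    rules = rules or default_rules()
    if not raw or not raw.strip():
        raise NormalizationError("empty temperature", raw)
    folded = _fold(raw)
    if folded in rules.temperature_aliases:
        return Quantity(rules.temperature_aliases[folded], CANONICAL_TEMP_UNIT, True)
    m = _TEMP_RE.match(raw.replace("℃", "°C").replace("°F", "F").replace("°C", "C"))
    if not m:
        raise NormalizationError(f"unparseable temperature: {raw!r}", raw)
    value = float(m.group("num"))
    unit = (m.group("unit") or "c").lower()
    if unit == "k":
        value -= 273.15
    elif unit == "f":
        value = (value - 32.0) * 5.0 / 9.0
    return Quantity(round(value, 10), CANONICAL_TEMP_UNIT, True)


def normalize_concentration(
    raw: str, rules: Optional[NormalizationRules] = None
) -> Quantity:
    """Normalize a concentration string; molar units are rescaled to µM.

    Units listed as non-convertible (mg/mL, % w/v, ...) are returned with
    their value and unit unchanged and ``convertible=False``.
    """
    rules = rules or default_rules()
    if not raw or not raw.strip():
        raise NormalizationError("empty concentration", raw)
    m = _CONC_RE.match(raw)
    if not m:
        raise NormalizationError(f"no parseable number in concentration: {raw!r}", raw)
    value = float(m.group("num"))
    unit = m.group("unit").strip()
    folded_unit = _fold(unit)
    if folded_unit in rules.molar_unit_factors:
        return Quantity(value * rules.molar_unit_factors[folded_unit],
                        CANONICAL_MOLAR_UNIT, True)
    if folded_unit in rules.non_convertible_units:
        return Quantity(value, unit, False)
    raise NormalizationError(f"unknown concentration unit: {unit!r}", raw)


def normalize_ph(raw: str) -> float:
    """Parse a pH string, stripping a leading "pH" token."""
    m = _PH_RE.match(raw or "")
    if not m:
        raise NormalizationError(f"unparseable pH: {raw!r}", raw)
    value = float(m.group("num"))
    if not (0.0 <= value <= 14.0):
        raise NormalizationError(f"pH out of range [0, 14]: {raw!r}", raw)
    return value


def normalize_phase(raw: str, rules: Optional[NormalizationRules] = None) -> int:
    """Map a free-text phase description to the binary phase status."""
    rules = rules or default_rules()
    folded = _fold(raw or "")
    if folded in rules.phase_vocab:
        return rules.phase_vocab[folded]
    raise NormalizationError(f"unknown phase-status token: {raw!r}", raw)


def canonicalize_protein_name(
    raw: str, rules: Optional[NormalizationRules] = None
) -> str:
    """Casefold, collapse whitespace, and resolve through the synonym map.

    Unknown names pass through after folding (total on non-empty text).
    """
    rules = rules or default_rules()
    folded = _fold(raw)
    return rules.protein_synonyms.get(folded, folded)


def normalize_record(
    rec: ExperimentRecord, rules: Optional[NormalizationRules] = None
) -> ExperimentRecord:
    """Normalize all present fields of a record; idempotent by construction.

    Per-field failures are not fatal: a quantity whose unit cannot be
    resolved keeps its value and is flagged non-convertible.
    """
    rules = rules or default_rules()
    changes: dict = {}
    if rec.protein_name is not None:
        changes["protein_name"] = canonicalize_protein_name(rec.protein_name, rules)
    for fname in ("protein_conc", "rna_conc"):
        q: Optional[Quantity] = getattr(rec, fname)
        if q is None:
            continue
        folded_unit = _fold(q.unit)
        if q.convertible and folded_unit == _fold(CANONICAL_MOLAR_UNIT):
            continue
        if folded_unit in rules.molar_unit_factors:
            changes[fname] = Quantity(
                q.value * rules.molar_unit_factors[folded_unit], CANONICAL_MOLAR_UNIT, True
            )
        else:
            # unknown or declared non-convertible: pass value/unit through
            changes[fname] = Quantity(q.value, q.unit, False)
    if rec.temperature is not None:
        t = rec.temperature
        if not (t.convertible and _fold(t.unit) == _fold(CANONICAL_TEMP_UNIT)):
            try:
                changes["temperature"] = normalize_temperature(
                    f"{t.value!r} {t.unit}", rules
                )
            except NormalizationError:
                changes["temperature"] = Quantity(t.value, t.unit, False)
    return rec.replace(**changes) if changes else rec
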