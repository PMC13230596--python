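"""Typed containers for LLPS experiment records and their tabular interchange.

An :class:`ExperimentRecord` carries the six experimental conditions commonly
reported for a liquid-liquid phase separation (LLPS) experiment — protein
name, protein concentration, RNA concentration, buffer pH, temperature and
binary phase status — plus auxiliary protein annotations and provenance
(which paper/figure the record came from).  Record sets round-trip losslessly
through CSV (RFC-4180, UTF-8, header row) and JSON (array of flat objects).

Missing values are an explicit ``None`` sentinel, distinct from an empty
string: the evaluator must distinguish "not extracted" from "extracted as
empty".  Concentrations are stored as :class:`Quantity` on the canonical µM
scale when convertible; non-convertible units (e.g. ``mg/mL``) keep their
value and unit with ``convertible=False``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "TARGET_FIELDS",
    "AUX_FIELDS",
    "CANONICAL_MOLAR_UNIT",
    "CANONICAL_TEMP_UNIT",
    "COLUMNS",
    "Quantity",
    "Provenance",
    "ExperimentRecord",
    "RecordSet",
    "RecordTableError",
    "read_record_table",
    "read_record_tables",
    "write_record_table",
]

#: The six evaluated experimental conditions, in canonical order.
TARGET_FIELDS = (
    "protein_name",
    "protein_conc",
    "rna_conc",
    "ph",
    "temperature",
    "phase_status",
)

#: Auxiliary protein annotations extracted but not scored.
AUX_FIELDS = ("sequence_region", "modification_state")

CANONICAL_MOLAR_UNIT = "µM"
CANONICAL_TEMP_UNIT = "°C"

#: Fixed ASCII column order for the tabular interchange formats.
COLUMNS = (
    "paper_id",
    "figure_id",
    "subfigure_id",
    "protein_name",
    "sequence_region",
    "modification_state",
    "protein_conc_um",
    "protein_conc_unit",
    "rna_conc_um",
    "rna_conc_unit",
    "ph",
    "temperature_c",
    "temperature_unit",
    "phase_status",
)


class RecordTableError(ValueError):
    """Raised when a record table cannot be parsed or violates invariants."""


@dataclass(frozen=True)
class Quantity:
    """A numeric value with a unit symbol.

    ``convertible=True`` means the value is on the canonical scale for its
    field (µM for concentrations, °C for temperature).  ``convertible=False``
    marks units such as mg/mL that cannot be rescaled to the canonical scale
    without extra information and are carried through unchanged.
    """

    value: float
    unit: str
    convertible: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"Quantity value must be finite, got {self.value!r}")
        if not self.unit:
            raise ValueError("Quantity unit must be non-empty")


@dataclass(frozen=True)
class Provenance:
    """Where a record came from: paper, figure and optional subfigure."""

    paper_id: str
    figure_id: Optional[str] = None
    subfigure_id: Optional[str] = None


@dataclass(frozen=True)
class ExperimentRecord:
    """One LLPS experiment: six target conditions plus auxiliary annotations."""

    provenance: Provenance
    protein_name: Optional[str] = None
    protein_conc: Optional[Quantity] = None
    rna_conc: Optional[Quantity] = None
    ph: Optional[float] = None
    temperature: Optional[Quantity] = None
    phase_status: Optional[int] = None
    sequence_region: Optional[str] = None
    modification_state: Optional[str] = None

    def __post_init__(self) -> None:
        if all(getattr(self, f) is None for f in TARGET_FIELDS):
            raise ValueError("record must have at least one of the six target fields")
        if self.ph is not None:
            if not math.isfinite(self.ph) or not (0.0 <= self.ph <= 14.0):
                raise ValueError(f"pH must be in [0, 14], got {self.ph!r}")
        if self.phase_status is not None and self.phase_status not in (0, 1):
            raise ValueError(f"phase_status must be 0 or 1, got {self.phase_status!r}")

    def present_fields(self) -> tuple[str, ...]:
        """Names of the target fields that are not missing."""
        return tuple(f for f in TARGET_FIELDS if getattr(self, f) is not None)

    def replace(self, **changes) -> "ExperimentRecord":
        return replace(self, **changes)


ScopeKey = tuple[str, Optional[str]]


@dataclass(frozen=True)
class RecordSet:
    """An ordered set of records sharing one evaluation scope.

    The scope is a figure (``figure_id`` set, figure-by-figure extraction) or
    a whole paper (``figure_id`` None, single-shot extraction).  Order is
    stable across serialization round-trips.
    """

    paper_id: str
    figure_id: Optional[str]
    records: tuple[ExperimentRecord, ...]
    origin: str = "label"
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in ("label", "extracted"):
            raise ValueError(f"origin must be 'label' or 'extracted', got {self.origin!r}")
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        for rec in self.records:
            if rec.provenance.paper_id != self.paper_id:
                raise ValueError(
                    f"record paper_id {rec.provenance.paper_id!r} does not match "
                    f"scope paper_id {self.paper_id!r}"
                )

    @property
    def scope(self) -> ScopeKey:
        return (self.paper_id, self.figure_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExperimentRecord]:
        return iter(self.records)


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _fmt_float(v: float) -> str:
    # repr() is the shortest string that round-trips the float exactly,
    # which keeps write->read->write byte-identical.
    return repr(float(v))


def _record_to_row(rec: ExperimentRecord) -> dict[str, str]:
    row = {c: "" for c in COLUMNS}
    row["paper_id"] = rec.provenance.paper_id
    row["figure_id"] = rec.provenance.figure_id or ""
    row["subfigure_id"] = rec.provenance.subfigure_id or ""
    if rec.protein_name is not None:
        row["protein_name"] = rec.protein_name
    if rec.sequence_region is not None:
        row["sequence_region"] = rec.sequence_region
    if rec.modification_state is not None:
        row["modification_state"] = rec.modification_state
    for fname, vcol, ucol in (
        ("protein_conc", "protein_conc_um", "protein_conc_unit"),
        ("rna_conc", "rna_conc_um", "rna_conc_unit"),
    ):
        q: Optional[Quantity] = getattr(rec, fname)
        if q is not None:
            row[vcol] = _fmt_float(q.value)
            # unit column left empty for canonical µM; filled for passthrough
            row[ucol] = "" if q.convertible else q.unit
    if rec.ph is not None:
        row["ph"] = _fmt_float(rec.ph)
    if rec.temperature is not None:
        row["temperature_c"] = _fmt_float(rec.temperature.value)
        row["temperature_unit"] = "" if rec.temperature.convertible else rec.temperature.unit
    if rec.phase_status is not None:
        row["phase_status"] = str(int(rec.phase_status))
    return row


def _parse_float(text: str, *, row_idx: int, col: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise RecordTableError(f"row {row_idx}: column {col!r}: not a number: {text!r}")
    if not math.isfinite(v):
        raise RecordTableError(f"row {row_idx}: column {col!r}: non-finite value {text!r}")
    return v


def _row_to_record(row: Mapping[str, str], row_idx: int) -> ExperimentRecord:
    unknown = set(row) - set(COLUMNS)
    if unknown:
        raise RecordTableError(
            f"row {row_idx}: unknown column(s) {sorted(unknown)}; "
            f"accepted columns are {list(COLUMNS)}"
        )
    get = lambda c: (row.get(c) or "").strip()
    paper_id = get("paper_id")
    if not paper_id:
        raise RecordTableError(f"row {row_idx}: column 'paper_id': must be non-empty")
    prov = Provenance(
        paper_id=paper_id,
        figure_id=get("figure_id") or None,
        subfigure_id=get("subfigure_id") or None,
    )
    kwargs: dict = {}
    for fname, vcol, ucol, canon in (
        ("protein_conc", "protein_conc_um", "protein_conc_unit", CANONICAL_MOLAR_UNIT),
        ("rna_conc", "rna_conc_um", "rna_conc_unit", CANONICAL_MOLAR_UNIT),
        ("temperature", "temperature_c", "temperature_unit", CANONICAL_TEMP_UNIT),
    ):
        vtxt, utxt = get(vcol), get(ucol)
        if vtxt:
            value = _parse_float(vtxt, row_idx=row_idx, col=vcol)
            if utxt:
                kwargs[fname] = Quantity(value, utxt, convertible=False)
            else:
                kwargs[fname] = Quantity(value, canon, convertible=True)
        elif utxt:
            raise RecordTableError(
                f"row {row_idx}: column {ucol!r}: unit given without a value"
            )
    if get("ph"):
        kwargs["ph"] = _parse_float(get("ph"), row_idx=row_idx, col="ph")
    if get("phase_status"):
        ptxt = get("phase_status")
        if ptxt not in ("0", "1"):
            raise RecordTableError(
                f"row {row_idx}: column 'phase_status': must be '0' or '1', got {ptxt!r}"
            )
        kwargs["phase_status"] = int(ptxt)
    for aux in ("protein_name",) + AUX_FIELDS:
        if get(aux):
            kwargs[aux] = get(aux)
    try:
        return ExperimentRecord(provenance=prov, **kwargs)
    except ValueError as exc:
        raise RecordTableError(f"row {row_idx}: {exc}") from exc


def _rows_to_sets(rows: Sequence[Mapping[str, str]], origin: str) -> list[RecordSet]:
    by_scope: dict[ScopeKey, list[ExperimentRecord]] = {}
    order: list[ScopeKey] = []
    for idx, row in enumerate(rows):
        rec = _row_to_record(row, idx)
        key = (rec.provenance.paper_id, rec.provenance.figure_id)
        if key not in by_scope:
            by_scope[key] = []
            order.append(key)
        by_scope[key].append(rec)
    return [
        RecordSet(paper_id=k[0], figure_id=k[1], records=tuple(by_scope[k]), origin=origin)
        for k in order
    ]


def read_record_tables(path: Union[str, Path], origin: str) -> list[RecordSet]:
    """Read a (possibly multi-scope) record table, grouped by scope.

    The format is chosen by extension: ``.csv`` or ``.json``.  Scopes are
    returned in first-appearance order; row order is preserved within each.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, list):
            raise RecordTableError("JSON record table must be an array of objects")
        rows = [{k: ("" if v is None else str(v)) for k, v in obj.items()} for obj in data]
    elif path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise RecordTableError("CSV record table must have a header row")
            unknown = set(reader.fieldnames) - set(COLUMNS)
            if unknown:
                raise RecordTableError(
                    f"unknown column(s) {sorted(unknown)}; accepted columns are {list(COLUMNS)}"
                )
            rows = [dict(r) for r in reader]
    else:
        raise RecordTableError(f"unsupported record-table extension: {path.suffix!r}")
    return _rows_to_sets(rows, origin)


def read_record_table(path: Union[str, Path], origin: str) -> RecordSet:
    """Read a single-scope record table (error if the file mixes scopes)."""
    sets = read_record_tables(path, origin)
    if not sets:
        raise RecordTableError(f"{path}: no records found")
    if len(sets) > 1:
        raise RecordTableError(
            f"{path}: contains {len(sets)} scopes; use read_record_tables()"
        )
    return sets[0]


def write_record_table(
    record_sets: Union[RecordSet, Sequence[RecordSet]], path: Union[str, Path]
) -> Path:
    """Write one or more record sets to CSV or JSON (chosen by extension).

    Column order is fixed (:data:`COLUMNS`); units are serialized alongside
    values for non-convertible quantities; re-reading yields an equal set and
    a second write is byte-identical.
    """
    if isinstance(record_sets, RecordSet):
        record_sets = [record_sets]
    path = Path(path)
    rows = [_record_to_row(rec) for rs in record_sets for rec in rs.records]
    if path.suffix.lower() == ".json":
        objs = []
        for row in rows:
            obj: dict = {}
            for col in COLUMNS:
                if row[col] == "":
                    continue
                if col in ("protein_conc_um", "rna_conc_um", "ph", "temperature_c"):
                    obj[col] = float(row[col])
                elif col == "phase_status":
                    obj[col] = int(row[col])
                else:
                    obj[col] = row[col]
            objs.append(obj)
        path.write_text(json.dumps(objs, ensure_ascii=False, indent=2) + "\n", encoding="utf-8")
    elif path.suffix.lower() == ".csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS, lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise RecordTableError(f"unsupported record-table extension: {path.suffix!r}")
    return path
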