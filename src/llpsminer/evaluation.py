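"""Assignment-based evaluation of extracted experiment records.

Extracted records and curated label records arrive in arbitrary order, so
scoring is a record-linkage problem: build a cost matrix whose entry (i, j)
is the mean per-field distance between extracted record i and label record
j, solve the minimum-cost one-to-one assignment (Hungarian method), then
classify every matched field by a distance threshold.

Distances, all on [0, 1]:

* numeric fields (concentrations, pH, temperature):
  ``|x_pred - x_true| / (x_max - x_min)`` where the range is the min/max of
  the *label* data in the evaluated scope (figure or paper); clamped to 1,
  and degenerate ranges (x_max == x_min) fall back to exact-match 0/1.
* text fields (protein name): ``1 - s`` with ``s`` the Ratcliff-Obershelp
  gestalt similarity (``difflib.SequenceMatcher`` ratio, no junk heuristic).
* phase status (binary): 0 on agreement, 1 on disagreement.

A matched field with distance strictly below the threshold (default 0.2) is
a true positive, otherwise a false positive; unmatched extracted fields are
false positives and unmatched label fields false negatives.  Per-field
precision, recall and F1 are computed per scope and averaged across scopes;
the overall Average is the mean of the six per-field means.  Paired method
comparison across scopes uses the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .records import (
    CANONICAL_MOLAR_UNIT,
    CANONICAL_TEMP_UNIT,
    TARGET_FIELDS,
    ExperimentRecord,
    Quantity,
    RecordSet,
    ScopeKey,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "FieldRange",
    "FieldRanges",
    "MatchedPair",
    "MatchResult",
    "FieldTally",
    "Metrics",
    "MetricsTable",
    "ScopeEvaluation",
    "EvaluationReport",
    "numeric_field_distance",
    "text_field_distance",
    "phase_field_distance",
    "field_pair_distance",
    "record_cost",
    "compute_field_ranges",
    "build_cost_matrix",
    "solve_assignment",
    "match_records",
    "classify_and_tally",
    "compute_prf",
    "aggregate_metrics",
    "evaluate_record_sets",
    "evaluate_paired",
    "threshold_sweep",
    "compare_methods_wilcoxon",
]

#: Matched fields with distance strictly below this count as true positives.
DEFAULT_THRESHOLD = 0.2

_NUMERIC_FIELDS = ("protein_conc", "rna_conc", "ph", "temperature")


def _fold_unit(unit: str) -> str:
    return " ".join(unit.casefold().split())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def numeric_field_distance(x_pred: float, x_true: float, x_min: float, x_max: float) -> float:
    """``|x_pred - x_true| / (x_max - x_min)``, clamped to [0, 1].

    The range comes from the label data of the evaluated scope.  When the
    range is degenerate (all labels share one value) the formula is
    undefined; exact-match semantics are preserved: 0 if equal, else 1.
    """
    if x_max < x_min:
        raise ValueError(f"invalid range: [{x_min}, {x_max}]")
    if x_max == x_min:
        return 0.0 if x_pred == x_true else 1.0
    return min(abs(x_pred - x_true) / (x_max - x_min), 1.0)


def text_field_distance(a: str, b: str) -> float:
    """``1 - s`` with s the Ratcliff-Obershelp gestalt similarity.

    ``s = 2M / (|a| + |b|)`` where M is the total length of matching blocks
    found recursively around longest matching substrings; s = 1 for an exact
    match.  The junk heuristic is disabled so short tokens score exactly.
    Comparison is case-insensitive (extracted names are casefolded during
    normalization; a pure case difference is not an extraction error), and
    the arguments are ordered canonically before matching — the gestalt
    ratio is order-dependent in rare cases, and a distance must be symmetric.
    """
    a, b = a.casefold(), b.casefold()
    if a == b:
        return 0.0
    if not a or not b:
        return 1.0
    x, y = (a, b) if a <= b else (b, a)
    return 1.0 - SequenceMatcher(None, x, y, autojunk=False).ratio()


def phase_field_distance(a: int, b: int) -> float:
    """0 for agreeing binary phase status, 1 for a mismatch."""
    return 0.0 if int(a) == int(b) else 1.0


@dataclass(frozen=True)
class FieldRange:
    """Min/max of the label data for one field (and unit class) in a scope."""

    field: str
    x_min: float
    x_max: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.x_min > self.x_max:
            raise ValueError("x_min must be <= x_max")


#: field name -> unit key -> FieldRange; unit key "" for plain floats (pH).
FieldRanges = Mapping[str, Mapping[str, FieldRange]]


def compute_field_ranges(labels: Iterable[ExperimentRecord]) -> FieldRanges:
    """Per-field min/max over the label records, keyed by unit class.

    Convertible quantities contribute to the canonical-unit range; each
    non-convertible unit (e.g. mg/mL) gets its own range, since values in
    different non-convertible units are not numerically comparable.
    """
    acc: dict[str, dict[str, list[float]]] = {f: {} for f in _NUMERIC_FIELDS}
    for rec in labels:
        for fname in _NUMERIC_FIELDS:
            val = getattr(rec, fname)
            if val is None:
                continue
            if isinstance(val, Quantity):
                key = (
                    _fold_unit(CANONICAL_MOLAR_UNIT if fname != "temperature" else CANONICAL_TEMP_UNIT)
                    if val.convertible
                    else _fold_unit(val.unit)
                )
                acc[fname].setdefault(key, []).append(val.value)
            else:
                acc[fname].setdefault("", []).append(float(val))
    return {
        fname: {
            key: FieldRange(fname, min(vs), max(vs), unit=key)
            for key, vs in units.items()
        }
        for fname, units in acc.items()
    }


def _quantity_distance(
    pred: Quantity, true: Quantity, fname: str, ranges: FieldRanges
) -> float:
    canon = CANONICAL_TEMP_UNIT if fname == "temperature" else CANONICAL_MOLAR_UNIT
    pred_key = _fold_unit(canon if pred.convertible else pred.unit)
    true_key = _fold_unit(canon if true.convertible else true.unit)
    if pred.convertible != true.convertible or pred_key != true_key:
        # one convertible and one not, or different passthrough units:
        # numeric comparison is meaningless -> maximal mismatch
        return 1.0
    fr = ranges.get(fname, {}).get(true_key)
    if fr is None:
        # no label defined a range for this unit class (can only happen for
        # extracted-only unit classes): exact-match semantics
        return 0.0 if pred.value == true.value else 1.0
    return numeric_field_distance(pred.value, true.value, fr.x_min, fr.x_max)


def field_pair_distance(
    extracted: ExperimentRecord,
    label: ExperimentRecord,
    fname: str,
    ranges: FieldRanges,
) -> Optional[float]:
    """Distance for one field of a record pair, or None if both missing.

    A field present on exactly one side scores the maximal distance 1 —
    omissions and hallucinations are penalized symmetrically.
    """
    e_val = getattr(extracted, fname)
    l_val = getattr(label, fname)
    if e_val is None and l_val is None:
        return None
    if e_val is None or l_val is None:
        return 1.0
    if fname == "protein_name":
        return text_field_distance(e_val, l_val)
    if fname == "phase_status":
        return phase_field_distance(e_val, l_val)
    if fname == "ph":
        fr = ranges.get("ph", {}).get("")
        if fr is None:
            return 0.0 if e_val == l_val else 1.0
        return numeric_field_distance(e_val, l_val, fr.x_min, fr.x_max)
    return _quantity_distance(e_val, l_val, fname, ranges)


def record_cost(
    extracted: ExperimentRecord, label: ExperimentRecord, ranges: FieldRanges
) -> float:
    """Mean of the six per-field distances (both-missing fields count 0)."""
    total = 0.0
    for fname in TARGET_FIELDS:
        d = field_pair_distance(extracted, label, fname, ranges)
        if d is not None:
            total += d
    return total / len(TARGET_FIELDS)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def build_cost_matrix(
    extracted: Sequence[ExperimentRecord],
    labels: Sequence[ExperimentRecord],
    ranges: Optional[FieldRanges] = None,
) -> np.ndarray:
    """Full |E| x |L| matrix of record costs (rows: extracted, cols: labels).

    Ranges default to being computed from the label records.  Either side
    empty yields a 0-sized matrix; the caller routes all records straight to
    false positives / false negatives.
    """
    if ranges is None:
        ranges = compute_field_ranges(labels)
    C = np.empty((len(extracted), len(labels)), dtype=float)
    for i, e in enumerate(extracted):
        for j, l in enumerate(labels):
            C[i, j] = record_cost(e, l, ranges)
    return C


@dataclass(frozen=True)
class MatchedPair:
    extracted_index: int
    label_index: int
    cost: float
    field_distances: Mapping[str, Optional[float]] = field(default_factory=dict)


@dataclass(frozen=True)
class MatchResult:
    """Optimal one-to-one matching plus the leftover indices on each side."""

    pairs: tuple[MatchedPair, ...]
    unmatched_extracted: tuple[int, ...]
    unmatched_labels: tuple[int, ...]

    @property
    def total_cost(self) -> float:
        return sum(p.cost for p in self.pairs)


# lexicographic tie-break: an infinitesimal bias with geometrically decaying
# row weights makes row 0's column choice dominate row 1's, and so on, so
# cost-equal optimal assignments resolve to the lowest (row, column) indices.
# A plain row-major bias would not work: a term separable as f(i) + g(j) sums
# to the same constant over every complete assignment.  The bias is far below
# any genuine cost difference, and totals are reported from the unbiased
# matrix.
_TIE_EPS = 1e-12


def solve_assignment(C: np.ndarray) -> MatchResult:
    """Minimum-total-cost one-to-one matching of min(|E|, |L|) pairs."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("cost matrix must be 2-dimensional")
    if C.size == 0:
        return MatchResult(
            pairs=(),
            unmatched_extracted=tuple(range(C.shape[0])),
            unmatched_labels=tuple(range(C.shape[1])),
        )
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix entries must be finite")
    n_rows, n_cols = C.shape
    decay = 1.0 / (2.0 * max(n_cols, 2))
    row_w = np.power(decay, np.arange(n_rows))
    bias = _TIE_EPS * row_w[:, None] * np.arange(n_cols)[None, :]
    rows, cols = linear_sum_assignment(C + bias)
    order = np.argsort(rows)
    pairs = tuple(
        MatchedPair(int(i), int(j), float(C[i, j]))
        for i, j in zip(rows[order], cols[order])
    )
    matched_rows = {p.extracted_index for p in pairs}
    matched_cols = {p.label_index for p in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_extracted=tuple(i for i in range(n_rows) if i not in matched_rows),
        unmatched_labels=tuple(j for j in range(n_cols) if j not in matched_cols),
    )


def match_records(
    extracted: Sequence[ExperimentRecord],
    labels: Sequence[ExperimentRecord],
    ranges: Optional[FieldRanges] = None,
) -> tuple[MatchResult, FieldRanges]:
    """Match record lists and attach per-field distances to each pair."""
    if ranges is None:
        ranges = compute_field_ranges(labels)
    C = build_cost_matrix(extracted, labels, ranges)
    result = solve_assignment(C)
    pairs = tuple(
        MatchedPair(
            p.extracted_index,
            p.label_index,
            p.cost,
            field_distances={
                f: field_pair_distance(extracted[p.extracted_index], labels[p.label_index], f, ranges)
                for f in TARGET_FIELDS
            },
        )
        for p in result.pairs
    )
    return (
        MatchResult(pairs, result.unmatched_extracted, result.unmatched_labels),
        ranges,
    )


# ---------------------------------------------------------------------------
# classification and metrics
# ---------------------------------------------------------------------------

@dataclass
class FieldTally:
    """True/false positive and false negative counts per target field."""

    tp: dict[str, int] = field(default_factory=lambda: {f: 0 for f in TARGET_FIELDS})
    fp: dict[str, int] = field(default_factory=lambda: {f: 0 for f in TARGET_FIELDS})
    fn: dict[str, int] = field(default_factory=lambda: {f: 0 for f in TARGET_FIELDS})

    def add(self, other: "FieldTally") -> "FieldTally":
        out = FieldTally()
        for f in TARGET_FIELDS:
            out.tp[f] = self.tp[f] + other.tp[f]
            out.fp[f] = self.fp[f] + other.fp[f]
            out.fn[f] = self.fn[f] + other.fn[f]
        return out

    def as_dict(self) -> dict[str, dict[str, int]]:
        return {
            f: {"tp": self.tp[f], "fp": self.fp[f], "fn": self.fn[f]}
            for f in TARGET_FIELDS
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FieldTally):
            return NotImplemented
        return self.tp == other.tp and self.fp == other.fp and self.fn == other.fn


def classify_and_tally(
    match: MatchResult,
    extracted: Sequence[ExperimentRecord],
    labels: Sequence[ExperimentRecord],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    strict_recall: bool = False,
    inclusive: bool = False,
) -> FieldTally:
    """Classify matched fields by the distance threshold and count.

    Per field: a matched pair with both sides present is a true positive
    when its distance is strictly below ``threshold``, otherwise a false
    positive; a field present only on the extracted side is a false
    positive; present only on the label side, a false negative.  Fields of
    unmatched extracted records are false positives and fields of unmatched
    labels false negatives.  ``strict_recall`` additionally counts an
    above-threshold matched field as a false negative (off by default,
    matching the precision-only reading of the thresholding rule);
    ``inclusive`` switches the comparison to <= (so exact matches survive a
    threshold of 0 in sensitivity sweeps).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    tally = FieldTally()
    for pair in match.pairs:
        e, l = extracted[pair.extracted_index], labels[pair.label_index]
        for fname in TARGET_FIELDS:
            e_present = getattr(e, fname) is not None
            l_present = getattr(l, fname) is not None
            if not e_present and not l_present:
                continue
            if e_present and not l_present:
                tally.fp[fname] += 1
            elif l_present and not e_present:
                tally.fn[fname] += 1
            else:
                d = pair.field_distances.get(fname)
                if d is None:
                    raise ValueError("match result lacks per-field distances; use match_records()")
                if d <= threshold if inclusive else d < threshold:
                    tally.tp[fname] += 1
                else:
                    tally.fp[fname] += 1
                    if strict_recall:
                        tally.fn[fname] += 1
    for i in match.unmatched_extracted:
        for fname in extracted[i].present_fields():
            tally.fp[fname] += 1
    for j in match.unmatched_labels:
        for fname in labels[j].present_fields():
            tally.fn[fname] += 1
    return tally


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F1 for one field; None where the denominator is 0."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def compute_prf(tally: FieldTally) -> dict[str, Metrics]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) per field.

    Zero-denominator cases are undefined (None) and later excluded from
    aggregation rather than imputed as 0.
    """
    out: dict[str, Metrics] = {}
    for f in TARGET_FIELDS:
        tp, fp, fn = tally.tp[f], tally.fp[f], tally.fn[f]
        p = tp / (tp + fp) if tp + fp > 0 else None
        r = tp / (tp + fn) if tp + fn > 0 else None
        if p is not None and r is not None and (p + r) > 0:
            f1: Optional[float] = 2 * p * r / (p + r)
        elif p is not None and r is not None:
            f1 = 0.0
        else:
            f1 = None
        out[f] = Metrics(p, r, f1)
    return out


def _mean_std(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass(frozen=True)
class MetricsTable:
    """Per-scope, per-field metrics with cross-scope aggregates.

    ``rows`` maps scope key -> field -> Metrics.  Aggregates: per-field mean
    and STD of F1 across the scopes where it is defined, and an overall
    Average equal to the mean of the six per-field means, with its STD taken
    across the per-scope averages.
    """

    rows: Mapping[ScopeKey, Mapping[str, Metrics]]

    @property
    def scopes(self) -> tuple[ScopeKey, ...]:
        return tuple(self.rows.keys())

    def scope_average_f1(self, scope: ScopeKey) -> Optional[float]:
        vals = [m.f1 for m in self.rows[scope].values() if m.f1 is not None]
        return float(np.mean(vals)) if vals else None

    def aggregate(self) -> dict:
        agg: dict = {"fields": {}, "n_scopes": len(self.rows)}
        field_means = []
        for f in TARGET_FIELDS:
            for metric in ("precision", "recall", "f1"):
                vals = [
                    getattr(row[f], metric)
                    for row in self.rows.values()
                    if getattr(row[f], metric) is not None
                ]
                mean, std = _mean_std(vals)
                entry = agg["fields"].setdefault(f, {})
                entry[f"{metric}_mean"] = mean
                entry[f"{metric}_std"] = std
                entry[f"{metric}_n_defined"] = len(vals)
            if agg["fields"][f]["f1_mean"] is not None:
                field_means.append(agg["fields"][f]["f1_mean"])
        agg["average_f1"] = float(np.mean(field_means)) if field_means else None
        scope_avgs = [
            a for a in (self.scope_average_f1(s) for s in self.scopes) if a is not None
        ]
        _, std = _mean_std(scope_avgs)
        agg["average_f1_std_across_scopes"] = std
        return agg

    def to_frame(self):
        """Long-format pandas DataFrame (scope x field grid)."""
        import pandas as pd

        recs = []
        for (paper_id, figure_id), row in self.rows.items():
            for f in TARGET_FIELDS:
                m = row[f]
                recs.append(
                    {
                        "paper_id": paper_id,
                        "figure_id": figure_id if figure_id is not None else "",
                        "field": f,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                    }
                )
        return pd.DataFrame.from_records(
            recs, columns=["paper_id", "figure_id", "field", "precision", "recall", "f1"]
        )

    def to_csv(self, path) -> None:
        """Deterministic CSV export of the scope x field grid."""
        frame = self.to_frame()
        frame.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def aggregate_metrics(table: MetricsTable) -> dict:
    """Cross-scope aggregation; see :meth:`MetricsTable.aggregate`."""
    return table.aggregate()


# ---------------------------------------------------------------------------
# scope-level driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScopeEvaluation:
    scope: ScopeKey
    match: MatchResult
    tally: FieldTally
    metrics: Mapping[str, Metrics]


def evaluate_record_sets(
    extracted: RecordSet,
    labels: RecordSet,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    strict_recall: bool = False,
    inclusive: bool = False,
) -> ScopeEvaluation:
    """Evaluate one scope: match, threshold-classify, and score."""
    if extracted.scope != labels.scope:
        raise ValueError(
            f"scope mismatch: extracted {extracted.scope} vs labels {labels.scope}"
        )
    match, _ = match_records(list(extracted), list(labels))
    tally = classify_and_tally(
        match, list(extracted), list(labels), threshold,
        strict_recall=strict_recall, inclusive=inclusive,
    )
    return ScopeEvaluation(labels.scope, match, tally, compute_prf(tally))


@dataclass(frozen=True)
class EvaluationReport:
    """Evaluation across scopes: per-scope details plus the metrics table."""

    threshold: float
    strict_recall: bool
    scope_evaluations: tuple[ScopeEvaluation, ...]
    table: MetricsTable

    @property
    def aggregate(self) -> dict:
        return self.table.aggregate()

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "strict_recall": self.strict_recall,
            "missing_field_convention": "missing-vs-present distance 1; cost averaged over six fields",
            "scopes": [
                {
                    "paper_id": ev.scope[0],
                    "figure_id": ev.scope[1],
                    "tally": ev.tally.as_dict(),
                    "pairs": [
                        {
                            "extracted_index": p.extracted_index,
                            "label_index": p.label_index,
                            "cost": p.cost,
                            "field_distances": dict(p.field_distances),
                        }
                        for p in ev.match.pairs
                    ],
                    "unmatched_extracted": list(ev.match.unmatched_extracted),
                    "unmatched_labels": list(ev.match.unmatched_labels),
                }
                for ev in self.scope_evaluations
            ],
            "aggregate": self.aggregate,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, ensure_ascii=False)
            fh.write("\n")


def evaluate_paired(
    extracted_sets: Sequence[RecordSet],
    label_sets: Sequence[RecordSet],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    strict_recall: bool = False,
    inclusive: bool = False,
) -> EvaluationReport:
    """Evaluate matching scopes from two collections of record sets.

    Scopes are paired by (paper_id, figure_id); a label scope with no
    extracted counterpart is evaluated against an empty extraction (all
    false negatives).  Extracted scopes without labels raise, since ranges
    cannot be computed.
    """
    by_scope = {rs.scope: rs for rs in extracted_sets}
    label_scopes = {rs.scope for rs in label_sets}
    orphans = sorted(set(by_scope) - label_scopes)
    if orphans:
        raise ValueError(f"extracted scopes without labels: {orphans}")
    evaluations = []
    rows: dict[ScopeKey, Mapping[str, Metrics]] = {}
    for labels in label_sets:
        extracted = by_scope.get(
            labels.scope,
            RecordSet(labels.paper_id, labels.figure_id, (), origin="extracted"),
        )
        ev = evaluate_record_sets(
            extracted, labels, threshold, strict_recall=strict_recall,
            inclusive=inclusive,
        )
        evaluations.append(ev)
        rows[labels.scope] = ev.metrics
    return EvaluationReport(threshold, strict_recall, tuple(evaluations), MetricsTable(rows))


def threshold_sweep(
    extracted_sets: Sequence[RecordSet],
    label_sets: Sequence[RecordSet],
    thresholds: Sequence[float],
    *,
    strict_recall: bool = False,
    inclusive: bool = False,
) -> dict[float, MetricsTable]:
    """Evaluate at several thresholds, computing each matching only once.

    The assignment is threshold-independent (costs do not involve the
    threshold), so the matching is reused across thresholds.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    by_scope = {rs.scope: rs for rs in extracted_sets}
    matches = []
    for labels in label_sets:
        extracted = by_scope.get(
            labels.scope,
            RecordSet(labels.paper_id, labels.figure_id, (), origin="extracted"),
        )
        match, _ = match_records(list(extracted), list(labels))
        matches.append((labels.scope, match, list(extracted), list(labels)))
    out: dict[float, MetricsTable] = {}
    for tau in thresholds:
        rows: dict[ScopeKey, Mapping[str, Metrics]] = {}
        for scope, match, ext, lab in matches:
            tally = classify_and_tally(
                match, ext, lab, tau, strict_recall=strict_recall, inclusive=inclusive
            )
            rows[scope] = compute_prf(tally)
        out[float(tau)] = MetricsTable(rows)
    return out


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    significant: bool  # at p < 0.05


def compare_methods_wilcoxon(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on per-scope scores.

    Zero differences are dropped (Wilcoxon convention); if every difference
    is zero the methods are indistinguishable and p = 1 with a warning.
    """
    if len(a) != len(b):
        raise ValueError("paired score lists must have equal length")
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p-value set to 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = _scipy_wilcoxon(
            nonzero, zero_method="wilcox", alternative="two-sided", method="auto"
        )
    return WilcoxonResult(float(stat), float(p), int(nonzero.size), bool(p < alpha))
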