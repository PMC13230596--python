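"""Synthetic LLPS label sets and controllably corrupted extractions.

The generator emulates the structure of a curated LLPS benchmark: each
figure holds a grid-like protein x RNA concentration sweep (a phase
diagram), with one protein, one buffer pH and one temperature per figure,
and a monotone phase rule (phase separation above a concentration-product
cutoff) so both outcomes appear.  Defaults mirror a realistic corpus scale
of 49 figures spread over 20 papers averaging ~18 experiments per figure.

``corrupt`` derives an "extracted" set from the labels by dropping records,
omitting fields, adding relative numeric noise, typo-ing protein names,
re-expressing concentrations in mM/nM (pre-normalization form), and
inserting spurious records — while tracking every change so the exact
true-positive / false-positive / false-negative tallies the evaluator must
produce are known *by construction*, without ever running the assignment
solver.

Exactness rests on two devices, checked at generation time:

* **Row dominance** — every corrupted record's cost to its true label is
  its row minimum, below every label outside an exactly-tied, provably
  tally-invariant tie set by a margin, so every optimal assignment yields
  the by-construction tallies.  Figures violating the condition are
  regenerated with a fresh corruption sub-seed and counted.
* **Constant-cost spurious rows** — spurious records are built so each of
  their field distances to *every* label is exactly 1 (alien protein name,
  out-of-range concentrations, off-grid pH/temperature, fields omitted
  where no such guarantee is possible), making their record cost exactly 1
  to all labels.  Whichever dropped labels they absorb, the tallies are
  identical.

Concentration grids are exact: labels on one grid line share the same
float value, so a corrupted record that omitted its one discriminating
field is *exactly* tied between those labels — with an identical distance
vector to each, which is what makes the tie tally-invariant.  Log-spaced
grid lines are separated by large factors, so the mild relative noise on
surviving values never moves a record closer to a neighbouring line than
to its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .evaluation import (
    FieldTally,
    build_cost_matrix,
    compute_field_ranges,
    field_pair_distance,
)
from .normalization import (
    NormalizationRules,
    canonicalize_protein_name,
    default_rules,
    normalize_concentration,
    normalize_ph,
    normalize_phase,
    normalize_temperature,
)
from .records import (
    TARGET_FIELDS,
    ExperimentRecord,
    Provenance,
    Quantity,
    RecordSet,
    ScopeKey,
)

__all__ = [
    "GeneratorConfig",
    "CorruptionConfig",
    "SyntheticScenario",
    "generate_labels",
    "corrupt",
    "make_scenario",
    "scenario_as_mock_script",
    "scenario_rules",
]

_DEFAULT_POOL = (
    "FUS",
    "TDP-43",
    "G3BP1",
    "HNRNPA1",
    "DDX4",
    "LAF-1",
    "PGL-3",
    "NPM1",
)

# spurious protein names use characters absent from every pool name and
# from the typo alphabet, forcing a gestalt similarity of exactly 0
_ALIEN_ALPHABET = "#@%&*+=?~"
_TYPO_ALPHABET = "abcdefghij"

_PHASE_TOKENS = {
    1: ("droplets", "phase separation", "condensates"),
    0: ("soluble", "one phase", "no phase separation"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Label-set generator settings; the defaults are the study conditions."""

    seed: int
    n_figures: int = 49
    n_papers: int = 20
    protein_pool: tuple = _DEFAULT_POOL
    protein_conc_bounds: tuple = (0.1, 100.0)  # µM, log-spaced grid
    rna_conc_bounds: tuple = (0.01, 50.0)  # µM
    grid_protein_points: tuple = (2, 6)  # inclusive draw range
    grid_rna_points: tuple = (2, 7)
    min_experiments_per_figure: int = 3
    max_experiments_per_figure: int = 40
    ph_values: tuple = (5.5, 6.5, 7.0, 7.4, 8.0)
    temperature_values: tuple = (4.0, 25.0, 25.0, 37.0)  # 25 repeated: RT common

    def __post_init__(self) -> None:
        if self.n_figures < 1 or self.n_papers < 1:
            raise ValueError("n_figures and n_papers must be >= 1")
        if not self.protein_pool or not self.ph_values or not self.temperature_values:
            raise ValueError("value pools must be non-empty")


@dataclass(frozen=True)
class CorruptionConfig:
    """Error-injection rates for deriving an extraction from labels.

    ``numeric_noise_sd`` is the relative (multiplicative) noise SD; a scalar
    applies to the two concentration fields (pH and temperature errors in
    real extractions are categorical, not jitter), a mapping sets each
    numeric field explicitly.
    """

    seed: int
    numeric_noise_sd: Union[float, Mapping[str, float]] = 0.05
    miss_field_rate: float = 0.05
    drop_record_rate: float = 0.05
    spurious_record_rate: float = 0.5  # expected spurious records per figure
    typo_rate: float = 0.05
    unit_jitter_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("miss_field_rate", "drop_record_rate", "typo_rate", "unit_jitter_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_record_rate < 0:
            raise ValueError("spurious_record_rate must be >= 0")

    def noise_sd(self, fname: str) -> float:
        if isinstance(self.numeric_noise_sd, Mapping):
            return float(self.numeric_noise_sd.get(fname, 0.0))
        return float(self.numeric_noise_sd) if fname in ("protein_conc", "rna_conc") else 0.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Labels, corrupted extraction, and the tallies the evaluator must find."""

    labels: tuple
    extracted: tuple
    expected_tallies: Mapping[ScopeKey, FieldTally]
    threshold: float
    raw_responses: Mapping[str, str]  # figure_id -> pre-normalization JSON text
    manifest: dict


def scenario_rules(protein_pool: Sequence[str]) -> NormalizationRules:
    """Normalization rules for a scenario: defaults plus an identity synonym
    map for the pool, so canonical names keep their original casing."""
    return default_rules().with_synonyms({name: name for name in protein_pool})


# ---------------------------------------------------------------------------
# label generation
# ---------------------------------------------------------------------------

def _log_grid(bounds: tuple, n: int) -> np.ndarray:
    lo, hi = bounds
    return np.exp(np.linspace(math.log(lo), math.log(hi), n))


def generate_labels(cfg: GeneratorConfig) -> list[RecordSet]:
    """Generate one label RecordSet per figure, deterministically from cfg.

    Each figure is a log-spaced concentration grid with phase = 1
    at or above the geometric-mean concentration-product cutoff, so both
    phase outcomes are present whenever the grid straddles the cutoff.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[RecordSet] = []
    for fig_idx in range(cfg.n_figures):
        paper_idx = fig_idx * cfg.n_papers // cfg.n_figures
        paper_id = f"P{paper_idx + 1:02d}"
        figure_id = f"Fig{fig_idx + 1}"
        while True:
            n_p = int(rng.integers(cfg.grid_protein_points[0], cfg.grid_protein_points[1] + 1))
            n_r = int(rng.integers(cfg.grid_rna_points[0], cfg.grid_rna_points[1] + 1))
            if cfg.min_experiments_per_figure <= n_p * n_r <= cfg.max_experiments_per_figure:
                break
        p_grid = _log_grid(cfg.protein_conc_bounds, n_p)
        r_grid = _log_grid(cfg.rna_conc_bounds, n_r)
        protein = cfg.protein_pool[int(rng.integers(len(cfg.protein_pool)))]
        ph = float(cfg.ph_values[int(rng.integers(len(cfg.ph_values)))])
        temp = float(cfg.temperature_values[int(rng.integers(len(cfg.temperature_values)))])
        pj = np.broadcast_to(p_grid[:, None], (n_p, n_r))
        rj = np.broadcast_to(r_grid[None, :], (n_p, n_r))
        products = pj * rj
        cutoff = float(np.exp(np.mean(np.log(products))))
        if np.all(products >= cutoff) or np.all(products < cutoff):
            import warnings

            warnings.warn(
                f"{figure_id}: degenerate grid; only one phase outcome", stacklevel=2
            )
        records = []
        for a in range(n_p):
            for b in range(n_r):
                records.append(
                    ExperimentRecord(
                        provenance=Provenance(paper_id, figure_id),
                        protein_name=protein,
                        protein_conc=Quantity(float(pj[a, b]), "µM", True),
                        rna_conc=Quantity(float(rj[a, b]), "µM", True),
                        ph=ph,
                        temperature=Quantity(temp, "°C", True),
                        phase_status=int(products[a, b] >= cutoff),
                    )
                )
        out.append(RecordSet(paper_id, figure_id, tuple(records), origin="label"))
    return out


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return repr(float(v))


def _corrupt_survivor(
    label: ExperimentRecord,
    ccfg: CorruptionConfig,
    rng: np.random.Generator,
    rules: NormalizationRules,
) -> Optional[dict]:
    """Raw (pre-normalization) JSON object for one surviving record, or None
    when field omission removed every target field (treated as a drop)."""
    raw: dict = {}
    miss = lambda: rng.random() < ccfg.miss_field_rate
    if label.protein_name is not None and not miss():
        name = label.protein_name
        if rng.random() < ccfg.typo_rate and len(name) > 1:
            pos = int(rng.integers(len(name)))
            ch = _TYPO_ALPHABET[int(rng.integers(len(_TYPO_ALPHABET)))]
            name = name[:pos] + ch + name[pos + 1:]
        raw["protein_name"] = name
    for fname, key in (("protein_conc", "protein_conc"), ("rna_conc", "rna_conc")):
        q = getattr(label, fname)
        if q is not None and not miss():
            sd = ccfg.noise_sd(fname)
            v = q.value
            if sd > 0:
                v = v * (1.0 + sd * rng.standard_normal())
                while v <= 0:  # resample pathological draws; concentrations are positive
                    v = q.value * (1.0 + sd * rng.standard_normal())
            if rng.random() < ccfg.unit_jitter_rate:
                unit, factor = ("mM", 1e3) if rng.random() < 0.5 else ("nM", 1e-3)
                raw[key] = f"{_fmt(v / factor)} {unit}"
            else:
                raw[key] = f"{_fmt(v)} µM"
    if label.ph is not None and not miss():
        v = label.ph
        sd = ccfg.noise_sd("ph")
        if sd > 0:
            v = float(np.clip(v * (1.0 + sd * rng.standard_normal()), 0.0, 14.0))
        raw["ph"] = f"pH {_fmt(v)}"
    if label.temperature is not None and not miss():
        v = label.temperature.value
        sd = ccfg.noise_sd("temperature")
        if sd > 0:
            v = v * (1.0 + sd * rng.standard_normal())
        if v == 25.0 and rng.random() < ccfg.unit_jitter_rate:
            raw["temperature"] = "RT"
        else:
            raw["temperature"] = f"{_fmt(v)} °C"
    if label.phase_status is not None and not miss():
        tokens = _PHASE_TOKENS[int(label.phase_status)]
        raw["phase_status"] = tokens[int(rng.integers(len(tokens)))]
    return raw or None


def _spurious_raw(
    labels: Sequence[ExperimentRecord],
    ranges,
    rng: np.random.Generator,
) -> dict:
    """A spurious record whose distance to *every* label is exactly 1 in each
    of its present fields; fields without such a guarantee are omitted (a
    missing-vs-present field also scores exactly 1)."""
    name = "".join(
        _ALIEN_ALPHABET[int(rng.integers(len(_ALIEN_ALPHABET)))] for _ in range(6)
    )
    raw = {"protein_name": name}
    for fname, key in (("protein_conc", "protein_conc"), ("rna_conc", "rna_conc")):
        fr = ranges.get(fname, {}).get("µm")
        if fr is not None:
            span = fr.x_max - fr.x_min
            v = fr.x_max + 2.0 * span if span > 0 else fr.x_max * 3.0 + 7.0
            raw[key] = f"{_fmt(v)} µM"
    fr = ranges.get("ph", {}).get("")
    if fr is not None:
        span = fr.x_max - fr.x_min
        if span > 0:
            for cand in (fr.x_max + 2.0 * span, fr.x_min - 2.0 * span):
                if 0.0 <= cand <= 14.0:
                    raw["ph"] = f"pH {_fmt(cand)}"
                    break
        else:
            cand = fr.x_max + 3.0 if fr.x_max + 3.0 <= 14.0 else fr.x_max - 3.0
            raw["ph"] = f"pH {_fmt(cand)}"
    fr = ranges.get("temperature", {}).get("°c")
    if fr is not None:
        span = fr.x_max - fr.x_min
        v = fr.x_max + 2.0 * span if span > 0 else fr.x_max + 31.0
        raw["temperature"] = f"{_fmt(v)} °C"
    # phase status omitted: no binary value is distant from both outcomes
    return raw


def _raw_to_record(
    raw: Mapping[str, str], prov: Provenance, rules: NormalizationRules
) -> ExperimentRecord:
    """Normalize a raw JSON object exactly as the extraction pipeline does."""
    kwargs: dict = {}
    if "protein_name" in raw:
        kwargs["protein_name"] = canonicalize_protein_name(raw["protein_name"], rules)
    if "protein_conc" in raw:
        kwargs["protein_conc"] = normalize_concentration(raw["protein_conc"], rules)
    if "rna_conc" in raw:
        kwargs["rna_conc"] = normalize_concentration(raw["rna_conc"], rules)
    if "ph" in raw:
        kwargs["ph"] = normalize_ph(raw["ph"])
    if "temperature" in raw:
        kwargs["temperature"] = normalize_temperature(raw["temperature"], rules)
    if "phase_status" in raw:
        kwargs["phase_status"] = normalize_phase(raw["phase_status"], rules)
    return ExperimentRecord(provenance=prov, **kwargs)


def _expected_figure_tally(
    survivor_pairs: Sequence[tuple],  # (extracted ExperimentRecord, label)
    n_spurious: int,
    spurious_present: Sequence[str],
    dropped: Sequence[ExperimentRecord],
    ranges,
    threshold: float,
) -> FieldTally:
    tally = FieldTally()
    for ext, lab in survivor_pairs:
        for fname in TARGET_FIELDS:
            e_present = getattr(ext, fname) is not None
            l_present = getattr(lab, fname) is not None
            if not e_present and not l_present:
                continue
            if e_present and not l_present:
                tally.fp[fname] += 1
            elif l_present and not e_present:
                tally.fn[fname] += 1
            else:
                d = field_pair_distance(ext, lab, fname, ranges)
                if d < threshold:
                    tally.tp[fname] += 1
                else:
                    tally.fp[fname] += 1
    n_dropped = len(dropped)
    n_absorbed = min(n_spurious, n_dropped)
    # spurious records matched to dropped labels: every present field is at
    # distance exactly 1 (>= any threshold in [0,1]) -> FP; every absent
    # field faces a present label field -> FN
    for _ in range(n_absorbed):
        for fname in TARGET_FIELDS:
            if fname in spurious_present:
                tally.fp[fname] += 1
            else:
                tally.fn[fname] += 1
    for _ in range(n_spurious - n_absorbed):  # unmatched spurious
        for fname in spurious_present:
            tally.fp[fname] += 1
    for lab in dropped[: n_dropped - n_absorbed]:  # unmatched dropped labels
        for fname in lab.present_fields():
            tally.fn[fname] += 1
    return tally


def corrupt(
    labels: Sequence[RecordSet],
    ccfg: CorruptionConfig,
    threshold: float = 0.2,
    *,
    rules: Optional[NormalizationRules] = None,
    dominance_margin: float = 1e-6,
    max_attempts: int = 200,
) -> SyntheticScenario:
    """Derive a corrupted extraction with exact by-construction tallies.

    Figures whose corrupted records violate the row-dominance margin (so the
    optimal assignment might not recover the true correspondence) are
    regenerated with a fresh sub-seed; the count is recorded in the manifest.
    """
    if rules is None:
        pool = sorted({r.protein_name for rs in labels for r in rs if r.protein_name})
        rules = default_rules().with_synonyms({n: n for n in pool})
    extracted_sets: list[RecordSet] = []
    expected: dict[ScopeKey, FieldTally] = {}
    raw_responses: dict[str, str] = {}
    regenerations = 0
    for fig_idx, label_set in enumerate(labels):
        lab_records = list(label_set)
        ranges = compute_field_ranges(lab_records)
        prov = Provenance(label_set.paper_id, label_set.figure_id)
        for attempt in range(max_attempts):
            rng = np.random.default_rng([ccfg.seed % (2**31), fig_idx, attempt])
            survivors: list[tuple[dict, int]] = []  # (raw object, true label idx)
            dropped: list[ExperimentRecord] = []
            for j, lab in enumerate(lab_records):
                if rng.random() < ccfg.drop_record_rate:
                    dropped.append(lab)
                    continue
                raw = _corrupt_survivor(lab, ccfg, rng, rules)
                if raw is None:
                    dropped.append(lab)
                else:
                    survivors.append((raw, j))
            n_spurious = int(rng.poisson(ccfg.spurious_record_rate))
            spurious = [_spurious_raw(lab_records, ranges, rng) for _ in range(n_spurious)]
            spurious_present = sorted(
                {f for s in spurious for f in s} | ({"protein_name"} if spurious else set()),
                key=TARGET_FIELDS.index,
            )
            entries = [(raw, j) for raw, j in survivors] + [(s, None) for s in spurious]
            order = rng.permutation(len(entries)) if entries else []
            shuffled = [entries[i] for i in order]
            ext_records = [
                _raw_to_record(raw, prov, rules) for raw, _ in shuffled
            ]
            if _dominance_ok(ext_records, [j for _, j in shuffled], lab_records, ranges,
                             dominance_margin):
                break
            regenerations += 1
        else:
            raise RuntimeError(
                f"{label_set.figure_id}: could not satisfy the separation margin "
                f"after {max_attempts} attempts; lower the corruption rates"
            )
        survivor_pairs = [
            (ext_records[i], lab_records[j])
            for i, (_, j) in enumerate(shuffled)
            if j is not None
        ]
        expected[label_set.scope] = _expected_figure_tally(
            survivor_pairs, n_spurious, spurious_present, dropped, ranges, threshold
        )
        extracted_sets.append(
            RecordSet(label_set.paper_id, label_set.figure_id, tuple(ext_records),
                      origin="extracted")
        )
        raw_responses[label_set.figure_id] = json.dumps(
            [raw for raw, _ in shuffled], indent=2, ensure_ascii=False
        )
    manifest = {
        "corruption_config": asdict(ccfg) if not isinstance(ccfg.numeric_noise_sd, Mapping)
        else {**asdict(ccfg), "numeric_noise_sd": dict(ccfg.numeric_noise_sd)},
        "threshold": threshold,
        "dominance_margin": dominance_margin,
        "figures_regenerated": regenerations,
        "n_figures": len(labels),
        "n_label_records": sum(len(rs) for rs in labels),
        "n_extracted_records": sum(len(rs) for rs in extracted_sets),
    }
    return SyntheticScenario(
        labels=tuple(labels),
        extracted=tuple(extracted_sets),
        expected_tallies=expected,
        threshold=threshold,
        raw_responses=raw_responses,
        manifest=manifest,
    )


def _dominance_ok(
    ext_records: Sequence[ExperimentRecord],
    true_idx: Sequence[Optional[int]],
    lab_records: Sequence[ExperimentRecord],
    ranges,
    margin: float,
) -> bool:
    """Check the separation conditions that make expected tallies exact.

    Each corrupted record must sit at its row minimum on its true label,
    strictly below (by the margin) every label outside its *tie set* — the
    labels at exactly the same cost.  Ties are tolerated only when they are
    tally-invariant: the per-field distance vector is identical across the
    tie set (a record that omitted every discriminating field is equally
    close to several labels, but scores the same against any of them), and
    all labels are complete, so whichever label ends up unmatched
    contributes the same false negatives.  Spurious rows must cost exactly
    1 everywhere.  Under these conditions every optimal assignment yields
    the by-construction tallies.
    """
    if not ext_records or not lab_records:
        return True
    eps = 1e-12
    for lab in lab_records:
        if len(lab.present_fields()) != len(TARGET_FIELDS):
            return False  # tie invariance needs interchangeable (complete) labels
    C = build_cost_matrix(ext_records, lab_records, ranges)
    for i, j in enumerate(true_idx):
        if j is None:
            if not np.all(np.abs(C[i] - 1.0) < eps):
                return False
            continue
        c_true = C[i, j]
        if c_true > 1.0 - margin:
            return False
        tie = [l for l in range(len(lab_records)) if abs(C[i, l] - c_true) <= eps]
        for l in range(len(lab_records)):
            if l not in tie and C[i, l] < c_true + margin:
                return False
        base = [
            field_pair_distance(ext_records[i], lab_records[j], f, ranges)
            for f in TARGET_FIELDS
        ]
        for l in tie:
            if l == j:
                continue
            for f, b in zip(TARGET_FIELDS, base):
                d = field_pair_distance(ext_records[i], lab_records[l], f, ranges)
                if (d is None) != (b is None) or (d is not None and abs(d - b) > eps):
                    return False
    return True


def make_scenario(
    gcfg: GeneratorConfig,
    ccfg: CorruptionConfig,
    threshold: float = 0.2,
    **kwargs,
) -> SyntheticScenario:
    """Generate labels and corrupt them in one step (pure in the configs)."""
    scenario = corrupt(generate_labels(gcfg), ccfg, threshold, **kwargs)
    scenario.manifest["generator_config"] = asdict(gcfg)
    return scenario


def scenario_as_mock_script(scenario: SyntheticScenario) -> dict[str, str]:
    """Per-figure model responses (fenced JSON) reproducing the scenario's
    extraction once parsed and normalized by the orchestration pipeline."""
    return {
        figure_id: f"```json\n{body}\n```"
        for figure_id, body in scenario.raw_responses.items()
    }
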