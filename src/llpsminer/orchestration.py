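"""Drive extraction runs: assemble inputs, call a backend, parse output.

A *paper bundle* holds everything one paper contributes: subfigure images,
caption+methods text, full text, and/or the PDF.  Four input patterns are
assembled from it — figure only, figure + caption/methods text, figure +
full text, and whole PDF.  The model behind a run is a pluggable *backend*:
any callable taking a :class:`BackendCall` and returning a
:class:`BackendResponse`.  Live vendor adapters are deliberately thin and
out of scope here; the scriptable :class:`MockBackend` replays canned
responses or a synthetic scenario, which makes the whole pipeline testable
offline and byte-for-byte deterministic.

Figure-by-figure runs issue exactly one backend call per figure directive
and scope each parsed record set to its figure; single-shot runs issue
exactly one call for the whole paper (PDF input, filter prompt) and scope
the records to the paper.  Backend failures are isolated: transport errors
are retried with exponential backoff, then recorded as an empty record set
with an error annotation — never a crashed run.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

from .normalization import (
    NormalizationError,
    NormalizationRules,
    canonicalize_protein_name,
    default_rules,
    normalize_concentration,
    normalize_ph,
    normalize_phase,
    normalize_temperature,
)
from .prompting import (
    FigureDirective,
    PromptBlocks,
    PromptVariant,
    compose_prompt,
    compose_single_shot_prompt,
)
from .records import ExperimentRecord, Provenance, Quantity, RecordSet

__all__ = [
    "InputPattern",
    "PaperBundle",
    "BackendCall",
    "BackendResponse",
    "Backend",
    "TransportError",
    "BundleError",
    "MockBackend",
    "assemble_input",
    "parse_model_output",
    "run_figure_by_figure",
    "run_single_shot",
]


class BundleError(ValueError):
    """A run requested bundle content the bundle does not provide."""


class TransportError(RuntimeError):
    """A retryable transport-level backend failure (network, rate limit)."""


from enum import Enum


class InputPattern(str, Enum):
    FIGURE = "figure"
    FIGURE_CM = "figure_cm"  # figure + caption/methods text
    FIGURE_FULLTEXT = "figure_fulltext"
    PDF = "pdf"


@dataclass(frozen=True)
class PaperBundle:
    """All extraction inputs available for one paper."""

    paper_id: str
    figures: tuple = ()  # of (FigureDirective, image path)
    pdf: Optional[Path] = None
    caption_method_text: Optional[str] = None
    full_text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.paper_id:
            raise ValueError("paper_id must be non-empty")
        object.__setattr__(self, "figures", tuple(self.figures))

    def check_pattern(self, pattern: InputPattern) -> None:
        """Validate that the bundle satisfies a pattern, before any call."""
        if pattern == InputPattern.PDF:
            if self.pdf is None:
                raise BundleError(f"{self.paper_id}: pattern 'pdf' needs a PDF file")
            return
        if not self.figures:
            raise BundleError(
                f"{self.paper_id}: pattern {pattern.value!r} needs figure images"
            )
        if pattern == InputPattern.FIGURE_CM and self.caption_method_text is None:
            raise BundleError(
                f"{self.paper_id}: pattern 'figure_cm' needs caption/methods text"
            )
        if pattern == InputPattern.FIGURE_FULLTEXT and self.full_text is None:
            raise BundleError(
                f"{self.paper_id}: pattern 'figure_fulltext' needs the full text"
            )


@dataclass(frozen=True)
class BackendCall:
    """One request to a model backend."""

    prompt: str
    attachments: tuple = ()  # of (kind: "image"|"pdf", path)
    model_name: str = "mock"
    sampling_temperature: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sampling_temperature <= 2.0):
            raise ValueError("sampling_temperature must be in [0, 2]")
        object.__setattr__(self, "attachments", tuple(self.attachments))


@dataclass(frozen=True)
class BackendResponse:
    """Verbatim model output plus optional accounting."""

    text: str
    token_counts: Optional[tuple] = None  # (input, output)
    latency_note: Optional[str] = None


Backend = Callable[[BackendCall], BackendResponse]


def assemble_input(
    bundle: PaperBundle,
    pattern: Union[InputPattern, str],
    directive: Optional[FigureDirective] = None,
) -> tuple:
    """Build (attachments, inlined_text) for a pattern; nothing else leaks.

    Figure-scoped patterns require a directive naming which figure image to
    attach; the PDF pattern takes the whole document and no directive.
    """
    pattern = InputPattern(pattern)
    bundle.check_pattern(pattern)
    if pattern == InputPattern.PDF:
        return (("pdf", bundle.pdf),), None
    if directive is None:
        raise BundleError(f"pattern {pattern.value!r} requires a figure directive")
    image = None
    for d, path in bundle.figures:
        if (d.figure_id, d.subfigure_id) == (directive.figure_id, directive.subfigure_id):
            image = path
            break
    if image is None:
        raise BundleError(
            f"{bundle.paper_id}: no image for figure {directive.figure_id!r} "
            f"(subfigure {directive.subfigure_id!r})"
        )
    attachments = (("image", image),)
    if pattern == InputPattern.FIGURE:
        return attachments, None
    if pattern == InputPattern.FIGURE_CM:
        return attachments, bundle.caption_method_text
    return attachments, bundle.full_text


# ---------------------------------------------------------------------------
# model-output parsing
# ---------------------------------------------------------------------------

_FENCE_RE = re.compile(r"```(?:json)?\s*(.*?)```", re.DOTALL)


def _first_json_array(text: str) -> Optional[list]:
    """Extract the first JSON array in the text; code fences stripped."""
    candidates = _FENCE_RE.findall(text)
    candidates.append(text)
    for cand in candidates:
        start = cand.find("[")
        if start < 0:
            continue
        decoder = json.JSONDecoder()
        try:
            value, _ = decoder.raw_decode(cand[start:])
        except json.JSONDecodeError:
            continue
        if isinstance(value, list):
            return value
    return None


_RAW_KEYS = {
    "protein_name",
    "protein_conc",
    "rna_conc",
    "ph",
    "temperature",
    "phase_status",
    "sequence_region",
    "modification_state",
}


def _object_to_record(
    obj: Mapping, prov: Provenance, rules: NormalizationRules, diagnostics: list
) -> Optional[ExperimentRecord]:
    kwargs: dict = {}
    unknown = sorted(set(obj) - _RAW_KEYS)
    if unknown:
        diagnostics.append(f"ignored unknown key(s): {unknown}")

    def norm(key: str, fn):
        raw = obj.get(key)
        if raw is None or (isinstance(raw, str) and not raw.strip()):
            return
        try:
            kwargs[key] = fn(str(raw))
        except NormalizationError as exc:
            diagnostics.append(f"{key}: {exc}")
            # keep the numeric part, flagged non-convertible, when possible
            if key in ("protein_conc", "rna_conc", "temperature"):
                m = re.match(r"\s*([-+]?\d+(?:\.\d+)?)", str(raw))
                if m:
                    kwargs[key] = Quantity(float(m.group(1)), str(raw).strip(), False)

    norm("protein_name", lambda s: canonicalize_protein_name(s, rules))
    norm("protein_conc", lambda s: normalize_concentration(s, rules))
    norm("rna_conc", lambda s: normalize_concentration(s, rules))
    norm("ph", normalize_ph)
    norm("temperature", lambda s: normalize_temperature(s, rules))
    norm("phase_status", lambda s: normalize_phase(s, rules))
    for aux in ("sequence_region", "modification_state"):
        raw = obj.get(aux)
        if isinstance(raw, str) and raw.strip():
            kwargs[aux] = raw.strip()
    try:
        return ExperimentRecord(provenance=prov, **kwargs)
    except ValueError as exc:
        diagnostics.append(f"skipped record: {exc}")
        return None


def parse_model_output(
    raw: str,
    paper_id: str = "unknown",
    figure_id: Optional[str] = None,
    rules: Optional[NormalizationRules] = None,
) -> RecordSet:
    """Parse raw model output into a normalized, scoped record set.

    Total on text: the first JSON array found is used (code fences are
    stripped); objects missing every target field are skipped and logged;
    non-JSON output yields an empty set with a diagnostic annotation.
    """
    rules = rules or default_rules()
    prov = Provenance(paper_id, figure_id)
    diagnostics: list[str] = []
    array = _first_json_array(raw or "")
    records: list[ExperimentRecord] = []
    if array is None:
        diagnostics.append("no JSON array found in model output")
    else:
        for obj in array:
            if not isinstance(obj, Mapping):
                diagnostics.append(f"skipped non-object entry: {obj!r}")
                continue
            rec = _object_to_record(obj, prov, rules, diagnostics)
            if rec is not None:
                records.append(rec)
    return RecordSet(
        paper_id, figure_id, tuple(records), origin="extracted",
        annotations=tuple(diagnostics),
    )


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

class MockBackend:
    """A deterministic, scriptable backend for offline runs and tests.

    Two scripting modes: canned responses keyed by ``figure_id`` (``None``
    for single-shot; build one backend per prompt variant for per-variant
    scripts), and *oracle mode* via :meth:`from_scenario`, replaying a
    synthetic scenario's corrupted extraction as fenced JSON.  Every call
    is recorded on ``calls``.
    """

    def __init__(
        self,
        responses: Mapping,
        *,
        fail_transport_times: int = 0,
    ):
        self._responses = dict(responses)
        self._fail_remaining = fail_transport_times
        self.calls: list[BackendCall] = []

    @classmethod
    def from_scenario(cls, scenario) -> "MockBackend":
        from .synthetic import scenario_as_mock_script

        return cls(scenario_as_mock_script(scenario))

    def _lookup(self, call: BackendCall) -> str:
        # the figure id is carried in the prompt's targeting directive;
        # match on the rendered sentence so "Fig1" never matches "Fig10"
        for fig, text in self._responses.items():
            if fig is None:
                continue
            if f"shown in {fig}." in call.prompt or f"shown in {fig}," in call.prompt:
                return text
        if None in self._responses:
            return self._responses[None]
        return ""

    def __call__(self, call: BackendCall) -> BackendResponse:
        self.calls.append(call)
        if self._fail_remaining > 0:
            self._fail_remaining -= 1
            raise TransportError("scripted transport failure")
        text = self._lookup(call)
        return BackendResponse(
            text=text, token_counts=(len(call.prompt.split()), len(text.split()))
        )


def _call_with_retries(
    backend: Backend,
    call: BackendCall,
    retries: int = 3,
    backoff: float = 0.1,
) -> BackendResponse:
    """Retry transport errors only, with exponential backoff; model-content
    errors are never retried (reproducibility)."""
    last: Optional[TransportError] = None
    for attempt in range(retries + 1):
        try:
            return backend(call)
        except TransportError as exc:
            last = exc
            if attempt < retries:
                time.sleep(backoff * (2**attempt))
    raise last  # type: ignore[misc]


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunSettings:
    model_name: str = "mock"
    sampling_temperature: float = 0.0
    seed: Optional[int] = None
    retries: int = 3
    backoff: float = 0.0


def run_figure_by_figure(
    bundle: PaperBundle,
    pattern: Union[InputPattern, str],
    blocks: PromptBlocks,
    variant: Union[PromptVariant, str],
    backend: Backend,
    *,
    rules: Optional[NormalizationRules] = None,
    settings: RunSettings = RunSettings(),
) -> list[RecordSet]:
    """One backend call per figure directive, in bundle order.

    Each response is parsed, normalized, and scoped to its figure; a figure
    whose call ultimately fails yields an empty annotated set, leaving the
    other figures untouched.
    """
    pattern = InputPattern(pattern)
    bundle.check_pattern(pattern)
    rules = rules or default_rules()
    out: list[RecordSet] = []
    for directive, _path in bundle.figures:
        attachments, inline_text = assemble_input(bundle, pattern, directive)
        prompt = compose_prompt(blocks, variant, directive)
        if inline_text is not None:
            prompt = f"{prompt}\n---\n{inline_text}\n"
        call = BackendCall(
            prompt=prompt,
            attachments=attachments,
            model_name=settings.model_name,
            sampling_temperature=settings.sampling_temperature,
            seed=settings.seed,
        )
        try:
            response = _call_with_retries(backend, call, settings.retries, settings.backoff)
        except TransportError as exc:
            out.append(
                RecordSet(
                    bundle.paper_id, directive.figure_id, (), origin="extracted",
                    annotations=(f"backend failure: {exc}",),
                )
            )
            continue
        out.append(
            parse_model_output(
                response.text, bundle.paper_id, directive.figure_id, rules
            )
        )
    return out


def run_single_shot(
    bundle: PaperBundle,
    blocks: PromptBlocks,
    backend: Backend,
    *,
    rules: Optional[NormalizationRules] = None,
    settings: RunSettings = RunSettings(),
) -> RecordSet:
    """Exactly one whole-paper call (PDF input, filter + full prompt);
    parsed records carry paper-level scope with no figure id."""
    bundle.check_pattern(InputPattern.PDF)
    rules = rules or default_rules()
    prompt = compose_single_shot_prompt(blocks)
    call = BackendCall(
        prompt=prompt,
        attachments=(("pdf", bundle.pdf),),
        model_name=settings.model_name,
        sampling_temperature=settings.sampling_temperature,
        seed=settings.seed,
    )
    try:
        response = _call_with_retries(backend, call, settings.retries, settings.backoff)
    except TransportError as exc:
        return RecordSet(
            bundle.paper_id, None, (), origin="extracted",
            annotations=(f"backend failure: {exc}",),
        )
    return parse_model_output(response.text, bundle.paper_id, None, rules)
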