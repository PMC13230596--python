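"""Composable prompt construction for the extraction runs.

Four prompt variants are built from configurable text blocks: a minimal
instruction block, an optional domain-knowledge (DK) block explaining LLPS
and each extraction item, an optional step-by-step extraction guide, and a
structured-output schema block.  Single-shot extraction prepends a filter
block with the target-experiment criteria to the full variant.  Figure-by-
figure runs append a targeting directive naming the figure (and, when a
subfigure holds several plots, its position).

Composition is a pure function of its inputs: identical blocks, variant and
directive yield byte-identical prompts.  The block wording is configuration,
not logic — the package ships plain-language defaults as text files.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "PromptVariant",
    "PromptBlocks",
    "FigureDirective",
    "PromptConfigurationError",
    "compose_prompt",
    "compose_single_shot_prompt",
]


class PromptConfigurationError(ValueError):
    """A variant requested a prompt block that is absent."""


class PromptVariant(str, Enum):
    MINIMAL = "minimal"
    MINIMAL_DK = "minimal_dk"
    MINIMAL_GUIDE = "minimal_guide"
    MINIMAL_DK_GUIDE = "minimal_dk_guide"

    @property
    def needs_dk(self) -> bool:
        return self in (PromptVariant.MINIMAL_DK, PromptVariant.MINIMAL_DK_GUIDE)

    @property
    def needs_guide(self) -> bool:
        return self in (PromptVariant.MINIMAL_GUIDE, PromptVariant.MINIMAL_DK_GUIDE)


def _load_block(name: str) -> str:
    return (resources.files("llpsminer.data") / "prompts" / f"{name}.txt").read_text(
        encoding="utf-8"
    )


@dataclass(frozen=True)
class PromptBlocks:
    """The text blocks prompts are composed from; ``minimal`` and
    ``output_schema`` are always present, the rest are optional."""

    minimal: str
    output_schema: str
    dk: Optional[str] = None
    guide: Optional[str] = None
    filter: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.minimal.strip():
            raise ValueError("minimal block must be non-empty")
        if not self.output_schema.strip():
            raise ValueError("output_schema block must be non-empty")

    @classmethod
    def default(cls) -> "PromptBlocks":
        """Blocks shipped with the package."""
        return cls(
            minimal=_load_block("minimal"),
            dk=_load_block("dk"),
            guide=_load_block("guide"),
            filter=_load_block("filter"),
            output_schema=_load_block("output_schema"),
        )

    @classmethod
    def from_files(
        cls,
        minimal: Union[str, Path],
        output_schema: Union[str, Path],
        dk: Optional[Union[str, Path]] = None,
        guide: Optional[Union[str, Path]] = None,
        filter: Optional[Union[str, Path]] = None,
    ) -> "PromptBlocks":
        read = lambda p: Path(p).read_text(encoding="utf-8")
        return cls(
            minimal=read(minimal),
            output_schema=read(output_schema),
            dk=read(dk) if dk else None,
            guide=read(guide) if guide else None,
            filter=read(filter) if filter else None,
        )


class Position(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    TOP = "top"
    BOTTOM = "bottom"
    NONE = "none"


@dataclass(frozen=True)
class FigureDirective:
    """Names the figure a prompt targets, optionally down to a subfigure and
    its position when several plots share one subfigure."""

    figure_id: str
    subfigure_id: Optional[str] = None
    position_qualifier: Position = Position.NONE

    def __post_init__(self) -> None:
        if not self.figure_id:
            raise ValueError("figure_id must be non-empty")
        if self.position_qualifier != Position.NONE and self.subfigure_id is None:
            raise ValueError("position qualifier requires a subfigure_id")

    def render(self) -> str:
        target = self.figure_id
        if self.subfigure_id:
            target = f"{target}, panel {self.subfigure_id}"
            if self.position_qualifier != Position.NONE:
                target = f"{target} ({self.position_qualifier.value} plot)"
        return (
            f"Extract only the experiments shown in {target}. "
            "Ignore all other figures."
        )


def _join(parts: list[str]) -> str:
    return "\n\n".join(p.strip() for p in parts if p) + "\n"


def compose_prompt(
    blocks: PromptBlocks,
    variant: Union[PromptVariant, str],
    directive: Optional[FigureDirective] = None,
) -> str:
    """Compose one of the four prompt variants.

    Deterministic concatenation in fixed order: minimal, DK, guide, output
    schema, then the figure directive.
    """
    variant = PromptVariant(variant)
    if variant.needs_dk and not (blocks.dk and blocks.dk.strip()):
        raise PromptConfigurationError(f"variant {variant.value!r} requires a DK block")
    if variant.needs_guide and not (blocks.guide and blocks.guide.strip()):
        raise PromptConfigurationError(f"variant {variant.value!r} requires a guide block")
    parts = [blocks.minimal]
    if variant.needs_dk:
        parts.append(blocks.dk)  # type: ignore[arg-type]
    if variant.needs_guide:
        parts.append(blocks.guide)  # type: ignore[arg-type]
    parts.append(blocks.output_schema)
    if directive is not None:
        parts.append(directive.render())
    return _join(parts)


def compose_single_shot_prompt(blocks: PromptBlocks) -> str:
    """Compose the whole-paper prompt: filter criteria + the full variant.

    Single-shot extraction has no figure directive; the filter block states
    which experiments qualify for extraction from the entire document.
    """
    if not (blocks.filter and blocks.filter.strip()):
        raise PromptConfigurationError("single-shot prompt requires a filter block")
    if not (blocks.dk and blocks.dk.strip()) or not (blocks.guide and blocks.guide.strip()):
        raise PromptConfigurationError(
            "single-shot prompt requires DK and guide blocks (full variant)"
        )
    return _join([blocks.filter, blocks.minimal, blocks.dk, blocks.guide, blocks.output_schema])
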