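"""Reading, validating and writing nested standoff annotations.

Documents are plain text plus brat-style standoff annotations: ``T`` lines
carry typed character spans, optional ``N`` lines link a span to a concept
identifier in a terminology.  Offsets are 0-based, half-open, over Unicode
code points.  After validation any two mention spans are either disjoint,
identical (with different categories), or properly nested — crossing
overlaps cannot be represented in the per-level encoding used downstream
and are dropped or rejected according to the chosen policy.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

from .scheme import SchemeHierarchy

logger = logging.getLogger(__name__)

OverlapPolicy = Literal["drop", "strict"]


class StandoffParseError(ValueError):
    """A standoff annotation line could not be parsed."""


class OffsetError(ValueError):
    """A span does not match the document text."""


class CrossingOverlapError(ValueError):
    """Two mentions overlap without nesting (strict policy)."""


@dataclass(frozen=True, order=True)
class Span:
    """A 0-based half-open character interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        """Strict containment: covers *other* and is longer."""
        return self.start <= other.start and other.end <= self.end and self != other

    def crosses(self, other: "Span") -> bool:
        """Overlap without identity or nesting in either direction."""
        if self.end <= other.start or other.end <= self.start:
            return False
        return not (self == other or self.contains(other) or other.contains(self))

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed, possibly nested text span; optionally linked to a concept."""

    span: Span
    category: str
    concept_id: str | None = None

    @property
    def start(self) -> int:
        return self.span.start

    @property
    def end(self) -> int:
        return self.span.end


@dataclass(frozen=True)
class AnnotatedDocument:
    """Document text plus a validated set of possibly-nested mentions."""

    doc_id: str
    text: str
    mentions: tuple[EntityMention, ...] = field(default_factory=tuple)

    def surface(self, mention: EntityMention) -> str:
        return self.text[mention.start : mention.end]


def _sort_key(m: EntityMention) -> tuple[int, int, str]:
    # start ascending, longer first, category for full determinism
    return (m.start, -len(m.span), m.category)


def validate_mentions(
    mentions: Iterable[EntityMention],
    text_len: int,
    policy: OverlapPolicy = "drop",
    doc_id: str = "?",
) -> tuple[EntityMention, ...]:
    """Enforce the disjoint-or-nested invariant.

    Identical (span, category) duplicates are removed; identical spans with
    different categories are kept.  A mention that crosses an already-kept
    mention is dropped with a warning (``policy="drop"``) or raises
    (``policy="strict"``).  Survivors are returned in canonical order
    (start ascending, longer first).
    """
    seen: set[tuple[Span, str]] = set()
    kept: list[EntityMention] = []
    for m in sorted(mentions, key=_sort_key):
        if m.end > text_len:
            raise OffsetError(f"{doc_id}: mention {m} exceeds text length {text_len}")
        if (m.span, m.category) in seen:
            continue
        crossing = next((k for k in kept if m.span.crosses(k.span)), None)
        if crossing is not None:
            if policy == "strict":
                raise CrossingOverlapError(
                    f"{doc_id}: {m} crosses {crossing}; not representable as nesting"
                )
            logger.warning("%s: dropping crossing mention %s (kept %s)", doc_id, m, crossing)
            continue
        seen.add((m.span, m.category))
        kept.append(m)
    return tuple(kept)


def read_standoff(
    txt_content: str,
    ann_content: str,
    scheme: SchemeHierarchy,
    policy: OverlapPolicy = "drop",
    doc_id: str = "doc",
) -> AnnotatedDocument:
    """Parse a brat ``.txt``/``.ann`` pair into a validated document.

    ``T`` lines (``Tn<TAB>Category start end<TAB>surface``) become mentions;
    ``N`` lines (``Nn<TAB>Reference Tn cui<TAB>label``) attach concept
    identifiers.  Categories are resolved through the scheme (aliases
    folded onto canonical labels); the surface string of every ``T`` line
    must equal ``txt_content[start:end]``.
    """
    mentions_by_tid: dict[str, EntityMention] = {}
    concept_by_tid: dict[str, str] = {}
    for lineno, raw in enumerate(ann_content.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) != 3:
                raise StandoffParseError(f"line {lineno}: expected 3 tab-fields, got {raw!r}")
            head = fields[1].split(" ")
            if len(head) != 3:
                raise StandoffParseError(
                    f"line {lineno}: expected 'Category start end', got {fields[1]!r}"
                )
            category, start_s, end_s = head
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise StandoffParseError(f"line {lineno}: bad offsets in {raw!r}") from exc
            category = scheme.canonical(category)  # raises SchemeError if unknown
            span = Span(start, end)
            if txt_content[start:end] != fields[2]:
                raise OffsetError(
                    f"line {lineno}: surface {fields[2]!r} != text[{start}:{end}] "
                    f"{txt_content[start:end]!r}"
                )
            mentions_by_tid[tag] = EntityMention(span, category)
        elif tag.startswith("N"):
            if len(fields) < 2:
                raise StandoffParseError(f"line {lineno}: malformed N-line {raw!r}")
            head = fields[1].split(" ")
            if len(head) != 3 or head[0] != "Reference":
                raise StandoffParseError(f"line {lineno}: malformed N-line {raw!r}")
            _, tid, cui = head
            concept_by_tid[tid] = cui
        else:
            # brat allows other line types (A, R, E ...); out of scope here
            logger.warning("%s: ignoring unsupported annotation line %r", doc_id, raw)
    for tid, cui in concept_by_tid.items():
        if tid in mentions_by_tid:
            mentions_by_tid[tid] = replace(mentions_by_tid[tid], concept_id=cui)
        else:
            raise StandoffParseError(f"N-line references unknown mention id {tid!r}")
    mentions = validate_mentions(
        mentions_by_tid.values(), len(txt_content), policy=policy, doc_id=doc_id
    )
    return AnnotatedDocument(doc_id=doc_id, text=txt_content, mentions=mentions)


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document back to a ``(.txt, .ann)`` content pair.

    Mentions are written in canonical order (start ascending, longer first)
    so that ``read_standoff(*write_standoff(doc))`` reproduces *doc* exactly.
    """
    lines: list[str] = []
    n_lines: list[str] = []
    for i, m in enumerate(sorted(doc.mentions, key=_sort_key), 1):
        surface = doc.surface(m)
        lines.append(f"T{i}\t{m.category} {m.start} {m.end}\t{surface}")
        if m.concept_id is not None:
            n_lines.append(f"N{len(n_lines) + 1}\tReference T{i} {m.concept_id}\t{surface}")
    ann = "".join(f"{l}\n" for l in lines + n_lines)
    return doc.text, ann


@dataclass(frozen=True)
class CorpusStatistics:
    """Per-category mention counts and the embedded-mention fraction."""

    category_counts: dict[str, int]
    total_mentions: int
    embedded_mentions: int
    embedded_fraction: float
    embedded_fraction_defined: bool

    def as_dict(self) -> dict:
        return {
            "category_counts": dict(sorted(self.category_counts.items())),
            "total_mentions": self.total_mentions,
            "embedded_mentions": self.embedded_mentions,
            "embedded_fraction": self.embedded_fraction,
            "embedded_fraction_defined": self.embedded_fraction_defined,
        }


def corpus_statistics(docs: Iterable[AnnotatedDocument]) -> CorpusStatistics:
    """Count mentions per category and the fraction strictly contained in
    another mention of the same document.

    An empty corpus reports fraction 0 with ``embedded_fraction_defined``
    set to False.
    """
    counts: Counter[str] = Counter()
    total = 0
    embedded = 0
    for doc in docs:
        counts.update(m.category for m in doc.mentions)
        total += len(doc.mentions)
        for m in doc.mentions:
            if any(other.span.contains(m.span) for other in doc.mentions):
                embedded += 1
    defined = total > 0
    return CorpusStatistics(
        category_counts=dict(counts),
        total_mentions=total,
        embedded_mentions=embedded,
        embedded_fraction=(embedded / total) if defined else 0.0,
        embedded_fraction_defined=defined,
    )
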