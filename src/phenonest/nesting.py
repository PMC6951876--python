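"""Nested mentions <-> per-level BIO label sequences.

Nesting levels are innermost-first: level 0 holds the most deeply embedded
mentions and feeds the first model layer; a mention's level is the length
of the longest chain of mentions strictly contained in it.  Mentions
sharing an identical span with different categories are placed on
consecutive levels in lexicographic category order (a convention — the
multi-category layering of same-span annotations is otherwise
underdetermined), so every level's mentions are pairwise disjoint.

Innermost / outermost / all entity subsets follow the usual definitions:
innermost mentions contain no other mention, outermost mentions are
contained in no other mention, and nesting-free mentions belong to both.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .standoff import AnnotatedDocument, EntityMention, Span

logger = logging.getLogger(__name__)

# words (incl. digits, so "FEV1" stays whole), hyphenated compounds kept
# whole, any other non-space character as its own token
_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:[-/][A-Za-z0-9_]+)*|[^\sA-Za-z0-9_]")


@dataclass(frozen=True)
class Token:
    """A surface string plus its character span in the document text."""

    surface: str
    span: Span


@dataclass(frozen=True)
class LevelledSentence:
    """Tokenized sentence with one BIO label sequence per nesting level."""

    tokens: tuple[Token, ...]
    levels: tuple[tuple[str, ...], ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def tokenize(text: str, offset: int = 0) -> tuple[Token, ...]:
    """Whitespace/punctuation tokenization with offset preservation."""
    return tuple(
        Token(m.group(), Span(m.start() + offset, m.end() + offset))
        for m in _TOKEN_RE.finditer(text)
    )


def split_sentences(text: str) -> tuple[Span, ...]:
    """Sentence spans: one per non-empty line of the document text."""
    spans = []
    pos = 0
    for line in text.split("\n"):
        stripped = line.strip()
        if stripped:
            start = pos + line.index(stripped)
            spans.append(Span(start, start + len(stripped)))
        pos += len(line) + 1
    return tuple(spans)


class NestingInvariantError(ValueError):
    """Mentions violate the disjoint-or-nested invariant."""


def assign_levels(mentions: Iterable[EntityMention]) -> dict[EntityMention, int]:
    """Map each mention to its nesting level (0 = innermost layer).

    Level = longest chain of strict containments below the mention; among
    mentions with identical spans, lexicographically later categories are
    stacked on higher levels.  Raises :class:`NestingInvariantError` on
    crossing overlaps.
    """
    ms = sorted(set(mentions), key=lambda m: (len(m.span), m.start, m.category))
    for i, a in enumerate(ms):
        for b in ms[:i]:
            if a.span.crosses(b.span):
                raise NestingInvariantError(f"{a} crosses {b}")
    levels: dict[EntityMention, int] = {}
    for m in ms:  # shorter mentions first, so containees are already levelled
        depth = 0
        for other, lvl in levels.items():
            if m.span.contains(other.span):
                depth = max(depth, lvl + 1)
            elif m.span == other.span and other.category < m.category:
                depth = max(depth, lvl + 1)
        levels[m] = depth
    return levels


def _token_range(span: Span, tokens: Sequence[Token]) -> tuple[int, int] | None:
    """Half-open token index range covering *span*, snapping boundaries
    that fall mid-token outward to the enclosing token (logged)."""
    idx = [i for i, t in enumerate(tokens) if t.span.overlaps(span)]
    if not idx:
        return None
    first, last = idx[0], idx[-1]
    if tokens[first].span.start != span.start or tokens[last].span.end != span.end:
        logger.warning(
            "snapping mention span [%d,%d) outward to token span [%d,%d)",
            span.start, span.end, tokens[first].span.start, tokens[last].span.end,
        )
    return first, last + 1


def encode_bio(
    tokens: Sequence[Token],
    mentions: Iterable[EntityMention],
    assignment: dict[EntityMention, int] | None = None,
    scheme_tag: str = "BIO",
) -> LevelledSentence:
    """Encode mentions as per-level BIO (or BIOES) label sequences.

    The number of levels is ``max assigned level + 1`` (at least 1).
    Mentions whose boundaries fall inside a token are snapped outward.
    """
    mentions = list(mentions)
    if assignment is None:
        assignment = assign_levels(mentions)
    n_levels = max(assignment.values(), default=-1) + 1 if mentions else 0
    n_levels = max(n_levels, 1)
    grid = [["O"] * len(tokens) for _ in range(n_levels)]
    for m in sorted(mentions, key=lambda m: (m.start, -len(m.span), m.category)):
        rng = _token_range(m.span, tokens)
        if rng is None:
            logger.warning("mention %s covers no token; dropped from encoding", m)
            continue
        first, stop = rng
        row = grid[assignment[m]]
        if any(row[i] != "O" for i in range(first, stop)):
            logger.warning("token collision on level %d for %s; dropped", assignment[m], m)
            continue
        if scheme_tag == "BIOES":
            if stop - first == 1:
                row[first] = f"S-{m.category}"
            else:
                row[first] = f"B-{m.category}"
                for i in range(first + 1, stop - 1):
                    row[i] = f"I-{m.category}"
                row[stop - 1] = f"E-{m.category}"
        else:
            row[first] = f"B-{m.category}"
            for i in range(first + 1, stop):
                row[i] = f"I-{m.category}"
    return LevelledSentence(tuple(tokens), tuple(tuple(r) for r in grid))


def decode_bio(labels: Sequence[str], tokens: Sequence[Token]) -> tuple[EntityMention, ...]:
    """Decode one BIO (or BIOES) label sequence back into mentions.

    Total function: an ``I`` (or ``E``) following ``O`` or a different
    category is repaired as ``B`` — the conventional BIO repair.
    """
    if len(labels) != len(tokens):
        raise ValueError(f"{len(labels)} labels for {len(tokens)} tokens")
    out: list[EntityMention] = []
    open_cat: str | None = None
    open_first = 0
    def close(last: int) -> None:
        nonlocal open_cat
        if open_cat is not None:
            out.append(
                EntityMention(Span(tokens[open_first].span.start, tokens[last].span.end), open_cat)
            )
            open_cat = None
    for i, label in enumerate(labels):
        if label == "O":
            close(i - 1)
            continue
        prefix, _, cat = label.partition("-")
        if prefix in ("B", "S") or open_cat != cat:
            close(i - 1)
            open_cat = cat
            open_first = i
        if prefix in ("E", "S"):
            close(i)
    close(len(labels) - 1)
    return tuple(out)


def innermost_set(mentions: Iterable[EntityMention]) -> frozenset[EntityMention]:
    """Mentions that strictly contain no other mention."""
    ms = set(mentions)
    return frozenset(m for m in ms if not any(m.span.contains(o.span) for o in ms))


def outermost_set(mentions: Iterable[EntityMention]) -> frozenset[EntityMention]:
    """Mentions strictly contained in no other mention."""
    ms = set(mentions)
    return frozenset(m for m in ms if not any(o.span.contains(m.span) for o in ms))


def all_set(mentions: Iterable[EntityMention]) -> frozenset[EntityMention]:
    return frozenset(mentions)


REGIMES = ("innermost", "outermost", "all")


def regime_set(mentions: Iterable[EntityMention], regime: str) -> frozenset[EntityMention]:
    """Dispatch on regime name ('innermost' | 'outermost' | 'all')."""
    if regime == "innermost":
        return innermost_set(mentions)
    if regime == "outermost":
        return outermost_set(mentions)
    if regime == "all":
        return all_set(mentions)
    raise ValueError(f"unknown regime {regime!r}")


def document_sentences(doc: AnnotatedDocument) -> list[LevelledSentence]:
    """Split a document into levelled sentences (one per text line).

    Each mention is encoded in the sentence that contains it; mentions
    crossing sentence boundaries are dropped with a warning.
    """
    out = []
    for sspan in split_sentences(doc.text):
        tokens = tokenize(doc.text[sspan.start : sspan.end], offset=sspan.start)
        if not tokens:
            continue
        inside = [m for m in doc.mentions if sspan.start <= m.start and m.end <= sspan.end]
        skipped = [m for m in doc.mentions if m.span.overlaps(sspan) and m not in inside]
        for m in skipped:
            logger.warning("%s: mention %s crosses a sentence boundary; dropped", doc.doc_id, m)
        out.append(encode_bio(tokens, inside))
    return out


def to_column_format(sentences: Iterable[LevelledSentence]) -> str:
    """One token per line, one BIO column per level, blank line between
    sentences — for interoperability with sequence-labeling tooling."""
    blocks = []
    for sent in sentences:
        width = max(len(sent.levels), 1)
        lines = []
        for i, tok in enumerate(sent.tokens):
            cols = [sent.levels[k][i] if k < len(sent.levels) else "O" for k in range(width)]
            lines.append("\t".join([tok.surface, *cols]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
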