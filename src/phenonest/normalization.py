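"""Rule-based entity normalization to a terminology.

A mention is linked to a concept identifier by generating semantically
consistent string variants with six techniques, applied in a fixed order —

1. acronym/abbreviation expansion        (``Type 2 DM`` -> ``Type 2 diabetes mellitus``)
2. plural-to-singular conversion          (``alveolar septa`` -> ``alveolar septum``)
3. English equivalents of neoclassical compounds
                                          (``blood leukocyte`` -> ``white blood cell``)
4. neoclassical equivalents of English terms
                                          (``pleural inflammation`` -> ``pleuritis``)
5. syntactic variation                    (``supplemental oxygen`` -> ``oxygen supplementation``)
6. synonym substitution                   (``worsening`` -> ``deterioration of``)

— and matching each variant, in generation order, against the preferred
labels and synonyms of a category-filtered terminology.  Variants compose
to depth 2 with a breadth cap, the original mention always comes first,
and the first variant with a terminology hit wins.  Matching is
case-insensitive after whitespace folding.  Mentions describing several
concepts at once are not split and simply fail to normalize.

The packaged terminology is a small synthetic mock (see
``data/mock_terminology.tsv``); real dictionaries are plugged in through
the same tab-separated file format.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .scheme import SchemeHierarchy

TECHNIQUES = (
    "abbreviation",
    "singular",
    "neoclassical_to_english",
    "english_to_neoclassical",
    "syntactic",
    "synonym",
)


def _fold(s: str) -> str:
    return " ".join(s.lower().split())


def _read_rows(path) -> list[list[str]]:
    # accepts a Path or an importlib.resources Traversable
    rows = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass(frozen=True)
class ConceptEntry:
    identifier: str
    preferred: str
    synonyms: tuple[str, ...]
    categories: frozenset[str]


class Terminology:
    """Concept dictionary with case-insensitive surface lookup."""

    def __init__(self, entries: Iterable[ConceptEntry]):
        self.entries: dict[str, ConceptEntry] = {}
        self._by_surface: dict[str, list[str]] = defaultdict(list)
        for e in entries:
            if e.identifier in self.entries:
                raise ValueError(f"duplicate concept identifier {e.identifier!r}")
            self.entries[e.identifier] = e
            for surface in (e.preferred, *e.synonyms):
                self._by_surface[_fold(surface)].append(e.identifier)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.entries

    def lookup(self, surface: str, category: str | None = None) -> str | None:
        """First concept identifier whose label/synonym matches *surface*,
        optionally restricted to entries tagged with *category*."""
        for ident in self._by_surface.get(_fold(surface), ()):
            if category is None or category in self.entries[ident].categories:
                return ident
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "Terminology":
        entries = []
        for row in _read_rows(Path(path)):
            if len(row) != 4:
                raise ValueError(f"terminology rows need 4 tab-fields, got {row!r}")
            ident, preferred, syns, cats = row
            entries.append(ConceptEntry(
                identifier=ident,
                preferred=preferred,
                synonyms=tuple(s for s in syns.split("|") if s and s != "-"),
                categories=frozenset(c for c in cats.split("|") if c),
            ))
        return cls(entries)


@dataclass(frozen=True)
class VariantRuleSet:
    """The declarative rule tables driving the six variant techniques."""

    abbreviations: dict[str, str]
    plural_word: dict[str, str]
    plural_suffix: tuple[tuple[str, str], ...]
    neo_to_english: tuple[tuple[str, str], ...]
    english_to_neo: tuple[tuple[str, str], ...]
    derivational: tuple[tuple[str, str], ...]
    synonyms: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_dir(cls, directory) -> "VariantRuleSet":
        """Load rule tables from a directory (a path or package resource)."""
        d = Path(directory) if isinstance(directory, (str, Path)) else directory
        abbrev = {_fold(r[0]): _fold(r[1]) for r in _read_rows(d / "abbreviations.tsv")}
        pw, ps = {}, []
        for row in _read_rows(d / "plural_rules.tsv"):
            kind, pattern = row[0], row[1]
            repl = row[2] if len(row) > 2 else ""
            if kind == "word":
                pw[pattern] = repl
            elif kind == "suffix":
                ps.append((pattern, repl))
            else:
                raise ValueError(f"unknown plural rule kind {kind!r}")
        n2e = tuple((_fold(r[0]), _fold(r[1])) for r in _read_rows(d / "neoclassical_to_english.tsv"))
        e2n = tuple((_fold(r[0]), _fold(r[1])) for r in _read_rows(d / "english_to_neoclassical.tsv"))
        deriv = tuple((_fold(r[0]), _fold(r[1])) for r in _read_rows(d / "syntactic_rules.tsv"))
        syns = tuple(
            (_fold(r[0]), tuple(_fold(x) for x in r[1].split("|")))
            for r in _read_rows(d / "synonyms.tsv")
        )
        return cls(abbrev, pw, tuple(ps), n2e, e2n, deriv, syns)


def default_rules() -> VariantRuleSet:
    """The packaged rule tables."""
    return VariantRuleSet.from_dir(resources.files("phenonest.data"))


def _sub_phrase(text: str, pattern: str, replacement: str) -> str | None:
    """Whole-word, case-insensitive phrase substitution; None if no match."""
    rx = re.compile(r"(?<![A-Za-z0-9])" + re.escape(pattern) + r"(?![A-Za-z0-9])", re.IGNORECASE)
    out, n = rx.subn(replacement, text)
    return _fold(out) if n else None


def _singularize_word(word: str, rules: VariantRuleSet) -> str:
    if word in rules.plural_word:
        return rules.plural_word[word]
    for suffix, repl in rules.plural_suffix:
        if word.endswith(suffix) and len(word) > len(suffix) + 1:
            if suffix == "s" and word[-2:] in ("ss", "us", "is"):
                continue
            return word[: -len(suffix)] + repl
    return word


def _technique_variants(text: str, technique: str, rules: VariantRuleSet) -> list[str]:
    """Variants (differing from *text*) produced by one technique."""
    out: list[str] = []
    if technique == "abbreviation":
        for short, expansion in rules.abbreviations.items():
            v = _sub_phrase(text, short, expansion)
            if v and v != text:
                out.append(v)
    elif technique == "singular":
        words = text.split()
        singular = [_singularize_word(w, rules) for w in words]
        if singular != words:
            out.append(" ".join(singular))
    elif technique in ("neoclassical_to_english", "english_to_neoclassical"):
        table = rules.neo_to_english if technique == "neoclassical_to_english" else rules.english_to_neo
        for pattern, repl in table:
            v = _sub_phrase(text, pattern, repl)
            if v and v != text:
                out.append(v)
    elif technique == "syntactic":
        words = text.split()
        for adj, noun in rules.derivational:
            v = _sub_phrase(text, adj, noun)
            if v and v != text:
                out.append(v)
            if len(words) > 1 and words[0] == adj:  # move-to-head
                out.append(" ".join(words[1:]) + " " + noun)
        if len(words) == 2:  # "A B" <-> "B of A"
            out.append(f"{words[1]} of {words[0]}")
        if len(words) == 3 and words[1] == "of":
            out.append(f"{words[2]} {words[0]}")
    elif technique == "synonym":
        for pattern, repls in rules.synonyms:
            for repl in repls:
                v = _sub_phrase(text, pattern, repl)
                if v and v != text:
                    out.append(v)
    else:
        raise ValueError(f"unknown technique {technique!r}")
    return out


def _generate(mention: str, rules: VariantRuleSet, max_variants: int,
              max_depth: int = 2) -> list[tuple[str, tuple[str, ...]]]:
    """Ordered (variant, technique trail) pairs; original first, duplicates
    removed keeping the first occurrence, breadth capped."""
    if not mention.strip():
        raise ValueError("empty mention")
    origin = _fold(mention)
    seen = {origin}
    out: list[tuple[str, tuple[str, ...]]] = [(origin, ())]
    frontier: list[tuple[str, tuple[str, ...]]] = [(origin, ())]
    for _depth in range(max_depth):
        nxt: list[tuple[str, tuple[str, ...]]] = []
        for text, trail in frontier:
            for technique in TECHNIQUES:
                for v in _technique_variants(text, technique, rules):
                    if v in seen or len(out) >= max_variants:
                        continue
                    seen.add(v)
                    rec = (v, trail + (technique,))
                    out.append(rec)
                    nxt.append(rec)
        frontier = nxt
        if not frontier or len(out) >= max_variants:
            break
    return out


def generate_variants(mention: str, rules: VariantRuleSet | None = None,
                      max_variants: int = 200) -> list[str]:
    """Ordered variant list for *mention* (the folded original comes first)."""
    rules = rules if rules is not None else default_rules()
    return [v for v, _ in _generate(mention, rules, max_variants)]


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of normalizing one mention: matched concept (or None) and
    the ordered trail of techniques that produced the matching variant
    (empty trail = direct match)."""

    mention: str
    category: str
    concept_id: str | None
    trail: tuple[str, ...] = ()
    matched_variant: str | None = None

    @property
    def normalized(self) -> bool:
        return self.concept_id is not None


def normalize_mention(
    mention: str,
    category: str,
    terminology: Terminology,
    rules: VariantRuleSet | None = None,
    scheme: SchemeHierarchy | None = None,
    max_variants: int = 200,
) -> NormalizationResult:
    """Normalize one mention against the category-filtered terminology.

    The first variant, in generation order, whose surface matches an entry
    tagged with the mention's category wins; no match yields an
    unnormalized result.  Raises :class:`SchemeError` for categories
    outside the scheme when one is supplied.
    """
    if scheme is not None:
        category = scheme.canonical(category)
    rules = rules if rules is not None else default_rules()
    for variant, trail in _generate(mention, rules, max_variants):
        ident = terminology.lookup(variant, category)
        if ident is not None:
            return NormalizationResult(mention, category, ident, trail, variant)
    return NormalizationResult(mention, category, None)


@dataclass(frozen=True)
class CoverageRow:
    category: str
    total: int
    normalized: int

    @property
    def percentage(self) -> float:
        return round(100.0 * self.normalized / self.total, 2) if self.total else 0.0

    @property
    def defined(self) -> bool:
        return self.total > 0


@dataclass(frozen=True)
class CoverageReport:
    """Per-category normalization coverage with a grand-total row."""

    rows: tuple[CoverageRow, ...] = field(default_factory=tuple)

    @property
    def total_row(self) -> CoverageRow:
        return CoverageRow(
            "Total",
            sum(r.total for r in self.rows),
            sum(r.normalized for r in self.rows),
        )

    def as_dict(self) -> dict:
        out = {
            r.category: {"total": r.total, "normalized": r.normalized,
                         "percentage": r.percentage}
            for r in self.rows
        }
        t = self.total_row
        out["Total"] = {"total": t.total, "normalized": t.normalized,
                        "percentage": t.percentage}
        return out

    def to_table(self) -> str:
        rows = [("Category", "Total", "Normalized", "%")]
        for r in (*self.rows, self.total_row):
            rows.append((r.category, str(r.total), str(r.normalized), f"{r.percentage:.2f}"))
        widths = [max(len(x[i]) for x in rows) for i in range(4)]
        lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
        lines.insert(1, "-" * len(lines[0]))
        return "\n".join(lines)


def coverage_report(results: Iterable[NormalizationResult]) -> CoverageReport:
    """Aggregate normalization results into per-category coverage."""
    totals: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for r in results:
        totals[r.category][0] += 1
        totals[r.category][1] += int(r.normalized)
    rows = tuple(CoverageRow(c, t, n) for c, (t, n) in sorted(totals.items()))
    return CoverageReport(rows)


def coverage_from_counts(counts: dict[str, tuple[int, int]]) -> CoverageReport:
    """Coverage report straight from (total, normalized) count pairs."""
    return CoverageReport(tuple(CoverageRow(c, t, n) for c, (t, n) in counts.items()))


def copd_corpus_counts() -> dict[str, tuple[int, int]]:
    """Published per-category normalization counts for the COPD phenotype
    corpus, in printed row order."""
    with resources.as_file(
        resources.files("phenonest.data") / "copd_normalization_counts.tsv"
    ) as p:
        rows = _read_rows(p)
    return {r[0]: (int(r[1]), int(r[2])) for r in rows}


def default_terminology() -> Terminology:
    """The packaged synthetic mock terminology."""
    with resources.as_file(resources.files("phenonest.data") / "mock_terminology.tsv") as p:
        return Terminology.from_file(p)
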