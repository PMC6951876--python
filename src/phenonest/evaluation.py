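"""Strict-match evaluation, inter-annotator agreement, and error taxonomy.

A prediction counts as a true positive only when both its character span
and its semantic category equal a gold annotation ("strict" matching).
Reports carry precision/recall/F per category and micro-averaged, for any
of three entity regimes — innermost, outermost, or all — where the regime
filters the *gold* side through the nesting definitions; the evaluated
system is expected to supply a prediction set appropriate to the regime.

Inter-annotator agreement is the micro-averaged F-score obtained by
treating one annotator as gold and the other as predictions; micro-F is
symmetric under swapping the roles (P and R exchange).

The error taxonomy buckets every non-exact prediction/gold pair by a
greedy one-to-one matching: exact matches first, then same-span/
different-category pairs (wrong type), then same-category pairs with
overlapping spans (largest overlap first, earliest start on ties), and
whatever remains is spurious (predictions) or missed (gold).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence

from .nesting import regime_set
from .standoff import AnnotatedDocument, EntityMention


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F as percentages, plus the underlying counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def precision_defined(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "f": round(self.f, 2),
        }


@dataclass(frozen=True)
class EvalReport:
    """Per-category and micro-averaged strict-match scores for one regime."""

    regime: str
    per_category: dict[str, PRF]
    micro: PRF

    def as_dict(self) -> dict:
        return {
            "regime": self.regime,
            "micro": self.micro.as_dict(),
            "per_category": {c: prf.as_dict() for c, prf in sorted(self.per_category.items())},
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_table(self) -> str:
        rows = [("Category", "P (%)", "R (%)", "F (%)", "TP", "FP", "FN")]
        for cat, prf in sorted(self.per_category.items()):
            rows.append((cat, f"{prf.precision:.2f}", f"{prf.recall:.2f}",
                         f"{prf.f:.2f}", str(prf.tp), str(prf.fp), str(prf.fn)))
        m = self.micro
        rows.append(("micro", f"{m.precision:.2f}", f"{m.recall:.2f}",
                     f"{m.f:.2f}", str(m.tp), str(m.fp), str(m.fn)))
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
        lines.insert(1, "-" * len(lines[0]))
        return "\n".join(lines)


def _as_doc_list(
    mentions: Sequence[Collection[EntityMention]] | Collection[EntityMention],
) -> list[frozenset[EntityMention]]:
    seq = list(mentions)
    if seq and isinstance(seq[0], EntityMention):
        return [frozenset(seq)]  # a single flat collection
    return [frozenset(doc) for doc in seq]


def strict_prf(
    gold: Sequence[Collection[EntityMention]] | Collection[EntityMention],
    predicted: Sequence[Collection[EntityMention]] | Collection[EntityMention],
    regime: str = "all",
) -> EvalReport:
    """Strict span+category matching, micro-averaged over documents.

    *gold* and *predicted* are parallel per-document mention collections
    (a single flat collection is treated as one document).  The regime
    filter is applied to the gold side; duplicates are removed.
    """
    gold_docs = _as_doc_list(gold)
    pred_docs = _as_doc_list(predicted)
    # an empty flat collection against per-document input: broadcast
    if not pred_docs and gold_docs:
        pred_docs = [frozenset()] * len(gold_docs)
    if not gold_docs and pred_docs:
        gold_docs = [frozenset()] * len(pred_docs)
    if len(gold_docs) != len(pred_docs):
        raise ValueError(f"{len(gold_docs)} gold documents vs {len(pred_docs)} predicted")
    tp: dict[str, int] = defaultdict(int)
    fp: dict[str, int] = defaultdict(int)
    fn: dict[str, int] = defaultdict(int)
    for g_doc, p_doc in zip(gold_docs, pred_docs):
        g = {(m.span, m.category) for m in regime_set(g_doc, regime)}
        p = {(m.span, m.category) for m in p_doc}
        for span, cat in g & p:
            tp[cat] += 1
        for span, cat in p - g:
            fp[cat] += 1
        for span, cat in g - p:
            fn[cat] += 1
    cats = set(tp) | set(fp) | set(fn)
    per_cat = {c: PRF(tp[c], fp[c], fn[c]) for c in cats}
    micro = PRF(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    return EvalReport(regime=regime, per_category=per_cat, micro=micro)


class AlignmentError(ValueError):
    """The two annotators' documents do not line up."""


def iaa_fscore(
    annotator_a: Sequence[AnnotatedDocument],
    annotator_b: Sequence[AnnotatedDocument],
) -> float:
    """Inter-annotator agreement as strict micro-averaged F (percent).

    Annotator A plays gold, B plays predictions; both must annotate the
    same document texts.
    """
    a_docs, b_docs = list(annotator_a), list(annotator_b)
    if len(a_docs) != len(b_docs):
        raise AlignmentError(f"{len(a_docs)} documents vs {len(b_docs)}")
    for da, db in zip(a_docs, b_docs):
        if da.text != db.text:
            raise AlignmentError(f"text mismatch on {da.doc_id!r} / {db.doc_id!r}")
    report = strict_prf([d.mentions for d in a_docs], [d.mentions for d in b_docs])
    return report.micro.f


@dataclass(frozen=True)
class ErrorBreakdown:
    """Counts of error kinds, keyed by category.

    ``wrong_type``, ``overlapping_span`` and ``missed`` are keyed by the
    gold category; ``spurious`` (predictions matching no gold) by the
    predicted category.  Exact matches are reported as ``correct``.
    """

    correct: dict[str, int] = field(default_factory=dict)
    wrong_type: dict[str, int] = field(default_factory=dict)
    overlapping_span: dict[str, int] = field(default_factory=dict)
    spurious: dict[str, int] = field(default_factory=dict)
    missed: dict[str, int] = field(default_factory=dict)

    def total(self, bucket: str) -> int:
        return sum(getattr(self, bucket).values())

    def as_dict(self) -> dict:
        return {
            b: dict(sorted(getattr(self, b).items()))
            for b in ("correct", "wrong_type", "overlapping_span", "spurious", "missed")
        }


def error_taxonomy(
    gold: Iterable[EntityMention],
    predicted: Iterable[EntityMention],
) -> ErrorBreakdown:
    """Greedy one-to-one error bucketing of a prediction set against gold.

    Every false positive and false negative lands in exactly one bucket,
    so TP + wrong_type + overlapping_span + spurious = |predicted| and
    TP + wrong_type + overlapping_span + missed = |gold|.
    """
    g = sorted({(m.span, m.category) for m in gold})
    p = sorted({(m.span, m.category) for m in predicted})
    out = ErrorBreakdown()
    def bump(bucket: dict[str, int], cat: str) -> None:
        bucket[cat] = bucket.get(cat, 0) + 1
    # 1. exact matches
    exact = set(g) & set(p)
    for span, cat in sorted(exact):
        bump(out.correct, cat)
    g = [m for m in g if m not in exact]
    p = [m for m in p if m not in exact]
    # 2. same span, different category
    for gi in list(g):
        match = next((pi for pi in p if pi[0] == gi[0]), None)
        if match is not None:
            bump(out.wrong_type, gi[1])
            g.remove(gi)
            p.remove(match)
    # 3. same category, overlapping span — largest overlap first, then
    #    earliest gold start
    pairs = []
    for gi in g:
        for pi in p:
            if gi[1] == pi[1] and gi[0].overlaps(pi[0]):
                ov = min(gi[0].end, pi[0].end) - max(gi[0].start, pi[0].start)
                pairs.append((-ov, gi[0].start, pi[0].start, gi, pi))
    used_g: set = set()
    used_p: set = set()
    for _, _, _, gi, pi in sorted(pairs):
        if gi in used_g or pi in used_p:
            continue
        bump(out.overlapping_span, gi[1])
        used_g.add(gi)
        used_p.add(pi)
    # 4. leftovers
    for span, cat in g:
        if (span, cat) not in used_g:
            bump(out.missed, cat)
    for span, cat in p:
        if (span, cat) not in used_p:
            bump(out.spurious, cat)
    return out
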