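"""Synthetic nested-annotation corpora with controlled structure.

Documents are built from deterministic phrase-slot templates, not a
language model: each sentence interleaves distractor tokens with entity
groups.  A group is either a single flat mention (a one-token condition,
sign/symptom, drug or test) or, with probability ``p_nest``, a nested
chain in which a constituent-concept mention is embedded inside a longer
phenotype mention (an anatomical term inside a condition, a drug inside a
treatment, a test inside a test result) — emulating corpora in which
roughly 29% of annotated mentions are embedded in a longer mention.
Chains extend to deeper nesting with probability ``p_nest`` per extra
level up to ``max_depth``.

Vocabulary defaults read like the COPD domain (emphysema, inhaled
corticosteroids, spirometry, ...) purely for cosmetics; token identity,
not realism, carries the label signal, which is what makes desk-scale
learnability runs meaningful.  Same seed, same corpus, byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nesting import assign_levels
from .standoff import AnnotatedDocument, EntityMention, Span, validate_mentions, write_standoff

DEFAULT_VOCAB: dict[str, tuple[str, ...]] = {
    "quality": ("chronic", "severe", "persistent", "progressive", "moderate", "mild"),
    "anatomical": ("pulmonary", "bronchial", "alveolar", "pleural", "cardiac",
                   "tracheal", "diaphragmatic", "vascular"),
    "condition": ("emphysema", "asthma", "bronchitis", "fibrosis", "pneumonia",
                  "hypertension", "atelectasis", "bronchiectasis"),
    "drug": ("corticosteroids", "salbutamol", "theophylline", "tiotropium",
             "prednisolone", "formoterol", "azithromycin"),
    "treatment_mod": ("inhaled", "oral", "nebulized", "combination", "maintenance"),
    "test": ("spirometry", "oximetry", "radiography", "plethysmography",
             "capnography", "bronchoscopy"),
    "result_mod": ("reduced", "increased", "abnormal", "impaired", "elevated"),
    "sign": ("cough", "dyspnea", "wheezing", "fatigue", "cyanosis", "tachypnea"),
    "distractor": ("the", "patient", "showed", "with", "during", "study",
                   "observed", "clinical", "baseline", "followup"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the corpus generator.

    ``p_nest`` is the probability that an entity group nests (and, per
    additional level, that the chain deepens); the default 0.41 with
    ``max_depth=2`` puts the expected embedded-mention fraction at
    0.41/1.41 ~= 0.29.
    """

    seed: int = 0
    n_documents: int = 20
    sentences_per_document: tuple[int, int] = (3, 6)
    groups_per_sentence: tuple[int, int] = (1, 2)
    p_nest: float = 0.41
    max_depth: int = 2
    distractor_rate: float = 0.6
    vocab: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_VOCAB))

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_nest <= 1.0):
            raise ValueError("p_nest must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for key in DEFAULT_VOCAB:
            if not self.vocab.get(key):
                raise ValueError(f"empty vocabulary for template slot {key!r}")

    @property
    def expected_embedded_fraction(self) -> float:
        """E[embedded]/E[total] under the truncated-geometric chain length."""
        p, d = self.p_nest, self.max_depth
        probs = [(p ** (k - 1)) * (1 - p) for k in range(1, d)] + [p ** (d - 1)]
        e_len = sum(pr * k for k, pr in enumerate(probs, start=1))
        return (e_len - 1.0) / e_len


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated documents plus their gold mention-level assignments."""

    documents: tuple[AnnotatedDocument, ...]
    levels: tuple[dict[EntityMention, int], ...]
    config: GeneratorConfig

    def write(self, directory: str | Path) -> None:
        """Emit brat .txt/.ann pairs and a provenance manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for doc in self.documents:
            txt, ann = write_standoff(doc)
            (directory / f"{doc.doc_id}.txt").write_text(txt, encoding="utf-8")
            (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")
        cfg = asdict(self.config)
        cfg["vocab"] = {k: list(v) for k, v in cfg["vocab"].items()}
        manifest = {"generator": "phenonest.synthetic", "config": cfg}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def _pick(rng: np.random.Generator, options: tuple[str, ...]) -> str:
    return options[int(rng.integers(len(options)))]


def _chain_length(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    length = 1
    while length < cfg.max_depth and rng.random() < cfg.p_nest:
        length += 1
    return length


def _phrase(rng: np.random.Generator, options: tuple[str, ...], max_len: int = 2) -> list[str]:
    n = 1 + int(rng.integers(max_len))
    return [_pick(rng, options) for _ in range(n)]


def _make_group(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[list[str], list[tuple[int, int, str]]]:
    """One entity group: tokens plus (first_token, last_token+1, category)
    mention specs ordered innermost-first.

    Nested phenotype phrases have variable-length constituents and an
    optional leading modifier inside the outer span, so outer boundaries
    are not a fixed function of two adjacent tokens — the regularity the
    layered model can recover by collapsing the inner mention first.
    """
    v = cfg.vocab
    length = _chain_length(rng, cfg)
    if length == 1:
        kind = _pick(rng, ("condition", "sign", "drug", "test"))
        cat = {"condition": "Condition", "sign": "SignOrSymptom",
               "drug": "Drug", "test": "Test"}[kind]
        return [_pick(rng, v[kind])], [(0, 1, cat)]
    if length == 2:
        kind = int(rng.integers(3))
        prefix = [_pick(rng, v["quality"])] if rng.random() < 0.5 else []
        p = len(prefix)
        if kind == 0:  # anatomical concept inside a condition
            inner = _phrase(rng, v["anatomical"])
            toks = prefix + inner + [_pick(rng, v["condition"])]
            return toks, [(p, p + len(inner), "AnatomicalConcept"),
                          (0, len(toks), "Condition")]
        if kind == 1:  # drug inside a treatment
            inner = _phrase(rng, v["drug"])
            toks = prefix + [_pick(rng, v["treatment_mod"])] + inner
            return toks, [(p + 1, p + 1 + len(inner), "Drug"),
                          (0, len(toks), "Treatment")]
        inner = _phrase(rng, v["test"])
        toks = prefix + [_pick(rng, v["result_mod"])] + inner
        return toks, [(p + 1, p + 1 + len(inner), "Test"),
                      (0, len(toks), "TestResult")]
    # depth >= 3: anatomical term inside a test inside a test result;
    # deeper chains prepend quality modifiers to the outermost span
    inner = _phrase(rng, v["anatomical"])
    toks = [_pick(rng, v["result_mod"]), *inner, _pick(rng, v["test"])]
    specs = [(1, 1 + len(inner), "AnatomicalConcept"),
             (1, len(toks), "Test"), (0, len(toks), "TestResult")]
    for extra in range(length - 3):
        toks.insert(0, _pick(rng, v["quality"]))
        specs = [(a + 1, b + 1, c) for a, b, c in specs]
        specs.append((0, len(toks), "Problem" if extra % 2 == 0 else "TestResult"))
    return toks, specs


def generate_corpus(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate a validated nested corpus, deterministic under the seed."""
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    docs: list[AnnotatedDocument] = []
    levels: list[dict[EntityMention, int]] = []
    for d in range(cfg.n_documents):
        lines: list[str] = []
        mentions: list[EntityMention] = []
        offset = 0
        n_sent = int(rng.integers(cfg.sentences_per_document[0],
                                  cfg.sentences_per_document[1] + 1))
        for _s in range(n_sent):
            words: list[str] = []
            def emit(word: str) -> tuple[int, int]:
                nonlocal offset
                if words:
                    offset += 1  # joining space
                start = offset
                words.append(word)
                offset += len(word)
                return start, offset
            def emit_distractors() -> None:
                # quality words also occur as plain unannotated context, so
                # whether a modifier opens a phenotype span depends on the
                # constituent that follows it, not on the word itself; a
                # quality word is never the last word before an entity group,
                # keeping the annotation consistent (modifier adjacent to a
                # phenotype phrase is always part of it)
                run: list[str] = []
                while rng.random() < cfg.distractor_rate:
                    pool = "quality" if rng.random() < 0.25 else "distractor"
                    run.append(_pick(rng, cfg.vocab[pool]))
                if run and run[-1] in cfg.vocab["quality"]:
                    run.append(_pick(rng, cfg.vocab["distractor"]))
                for word in run:
                    emit(word)
            n_groups = int(rng.integers(cfg.groups_per_sentence[0],
                                        cfg.groups_per_sentence[1] + 1))
            emit_distractors()
            for g in range(n_groups):
                toks, specs = _make_group(rng, cfg)
                tok_spans = [emit(t) for t in toks]
                for a, b, cat in specs:
                    mentions.append(EntityMention(
                        Span(tok_spans[a][0], tok_spans[b - 1][1]), cat))
                if g + 1 < n_groups:
                    # consecutive entity groups are always separated by at
                    # least one plain word, as in running prose
                    emit(_pick(rng, cfg.vocab["distractor"]))
                emit_distractors()
            emit(".")
            lines.append(" ".join(words))
            offset += 1  # newline
        text = "\n".join(lines) + "\n"
        validated = validate_mentions(mentions, len(text), policy="strict",
                                      doc_id=f"synth{d:04d}")
        doc = AnnotatedDocument(doc_id=f"synth{d:04d}", text=text, mentions=validated)
        docs.append(doc)
        levels.append(assign_levels(doc.mentions))
    return SyntheticCorpus(tuple(docs), tuple(levels), cfg)


def generate_annotator_pair(
    config: GeneratorConfig | None = None,
    span_shift_rate: float = 0.0,
    relabel_rate: float = 0.0,
    drop_rate: float = 0.0,
    categories: tuple[str, ...] = ("Condition", "SignOrSymptom", "Drug", "Test",
                                   "Treatment", "TestResult", "AnatomicalConcept"),
) -> tuple[tuple[AnnotatedDocument, ...], tuple[AnnotatedDocument, ...]]:
    """Two annotation sets over identical texts.

    Annotator B is a seeded perturbation of annotator A: each mention is
    independently dropped, relabeled (to a different category) and/or
    span-shifted by one token edge.  A shift that would break the
    disjoint-or-nested invariant, leave the text, or collide with an
    existing mention is skipped.  All rates 0 gives identical sets.
    """
    for rate in (span_shift_rate, relabel_rate, drop_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    cfg = config if config is not None else GeneratorConfig()
    corpus = generate_corpus(cfg)
    rng = np.random.default_rng(cfg.seed + 104729)  # independent of generation
    b_docs: list[AnnotatedDocument] = []
    for doc in corpus.documents:
        kept: list[EntityMention] = []
        for m in doc.mentions:
            if rng.random() < drop_rate:
                continue
            category = m.category
            if rng.random() < relabel_rate:
                others = [c for c in categories if c != m.category]
                category = others[int(rng.integers(len(others)))]
            span = m.span
            if rng.random() < span_shift_rate:
                span = _shift_span(rng, doc, m.span)
            cand = EntityMention(span, category)
            existing = set(kept)
            if cand in existing or any(cand.span.crosses(k.span) for k in kept):
                cand = EntityMention(m.span, category)  # undo the shift
                if cand in existing:
                    continue
            kept.append(cand)
        b_docs.append(AnnotatedDocument(
            doc_id=doc.doc_id, text=doc.text,
            mentions=validate_mentions(kept, len(doc.text), policy="drop",
                                       doc_id=doc.doc_id)))
    return corpus.documents, tuple(b_docs)


def _shift_span(rng: np.random.Generator, doc: AnnotatedDocument, span: Span) -> Span:
    """Move one span edge outward/inward by one whitespace-delimited token."""
    from .nesting import split_sentences, tokenize
    for sspan in split_sentences(doc.text):
        if sspan.start <= span.start and span.end <= sspan.end:
            tokens = tokenize(doc.text[sspan.start:sspan.end], offset=sspan.start)
            starts = [t.span.start for t in tokens]
            ends = [t.span.end for t in tokens]
            moves = []
            if span.start in starts and starts.index(span.start) > 0:
                moves.append(Span(starts[starts.index(span.start) - 1], span.end))
            if span.end in ends and ends.index(span.end) + 1 < len(ends):
                moves.append(Span(span.start, ends[ends.index(span.end) + 1]))
            if moves:
                return moves[int(rng.integers(len(moves)))]
    return span
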