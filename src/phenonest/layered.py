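"""Dynamically stacked BiLSTM-CRF layers for nested entity recognition.

Each layer runs a BiLSTM-CRF over the current unit sequence (tokens at the
first layer).  Every entity the layer detects is collapsed into a single
unit whose representation is the element-wise average of the contextual
states of its constituent units; non-entity units pass through unchanged.
The shortened sequence feeds the next layer, so entities that enclose
already-detected ones become contiguous and recognizable.  Stacking stops
when a newly applied layer detects nothing (or at the layer cap), and the
output is the union over layers of all decoded mentions, mapped back to
character spans of the original text and deduplicated on (span, category).

At training time the next layer's input is built from the *gold*
lower-level regions by default (teacher forcing); a config flag switches
to model-predicted regions.  Training appends one extra all-outside layer
beyond the deepest gold nesting level so the model learns to terminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .nesting import LevelledSentence, Token, decode_bio
from .standoff import AnnotatedDocument, EntityMention, Span
from .tagger import (
    Adam,
    BiLSTMLayer,
    CRFHead,
    TaggerConfig,
    TokenEncoder,
    Vocabulary,
    bio_tag_names,
)

logger = logging.getLogger(__name__)


def merge_region(states: Tensor) -> Tensor:
    """Element-wise average of a region's unit states: ``(n, D) -> (1, D)``.

    A single-unit region returns that unit's state unchanged.
    """
    n = states.shape[0]
    if n == 0:
        raise ValueError("cannot merge an empty region")
    return Tensor(np.full((1, n), 1.0 / n)) @ states


def _label_runs(labels: list[str]) -> list[tuple[int, int, str]]:
    """Maximal B-I runs as (start, stop, category), with BIO repair."""
    runs: list[tuple[int, int, str]] = []
    open_cat, open_at = None, 0
    for i, label in enumerate(labels):
        prefix, _, cat = label.partition("-")
        if label == "O" or prefix == "B" or (open_cat is not None and cat != open_cat):
            if open_cat is not None:
                runs.append((open_at, i, open_cat))
                open_cat = None
        if label != "O" and open_cat is None:
            open_cat, open_at = cat, i
    if open_cat is not None:
        runs.append((open_at, len(labels), open_cat))
    return runs


def build_next_layer_input(
    states: Tensor,
    unit_spans: list[tuple[int, int]],
    regions: list[tuple[int, int, str]],
) -> tuple[Tensor, list[tuple[int, int]]]:
    """Collapse each detected region into one averaged unit.

    *unit_spans* are half-open token-index ranges for the current units;
    the returned spans compose the collapse so they always map back to
    original-token ranges.  Regions must be pairwise disjoint (guaranteed
    by CRF decoding, asserted here).
    """
    for (a, b, _), (c, d, _) in zip(regions, regions[1:]):
        assert b <= c or d <= a, "decoded regions must be disjoint"
    regions = sorted(regions)
    U = len(unit_spans)
    rows: list[np.ndarray] = []
    new_spans: list[tuple[int, int]] = []
    pos = 0
    def passthrough(stop: int) -> None:
        nonlocal pos
        while pos < stop:
            row = np.zeros(U)
            row[pos] = 1.0
            rows.append(row)
            new_spans.append(unit_spans[pos])
            pos += 1
    for a, b, _cat in regions:
        passthrough(a)
        row = np.zeros(U)
        row[a:b] = 1.0 / (b - a)
        rows.append(row)
        new_spans.append((unit_spans[a][0], unit_spans[b - 1][1]))
        pos = b
    passthrough(U)
    return Tensor(np.array(rows)) @ states, new_spans


@dataclass
class LayerTrace:
    """Per-layer decoded unit labels and unit -> token-range mappings."""

    unit_labels: list[list[str]] = field(default_factory=list)
    unit_spans: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.unit_labels)


class LayeredTagger:
    """A stack of BiLSTM-CRF layers over a shared token encoder.

    ``n_layers == 1`` is the flat (non-layered) baseline.
    """

    def __init__(
        self,
        config: TaggerConfig,
        categories: list[str],
        n_layers: int,
        vocab: Vocabulary,
        pretrained: dict[str, np.ndarray] | None = None,
    ):
        if n_layers < 1:
            raise ValueError("need at least one layer")
        self.config = config
        self.categories = sorted(categories)
        self.tag_names = bio_tag_names(self.categories, config.scheme_tag)
        self.n_layers = n_layers
        rng = np.random.default_rng(config.seed)
        self.encoder = TokenEncoder(config, vocab, rng, pretrained)
        self.layers: list[tuple[BiLSTMLayer, CRFHead]] = []
        for k in range(n_layers):
            if config.share_layers and k >= 2:
                self.layers.append(self.layers[1])  # layers 1..n share params
                continue
            din = self.encoder.out_dim if k == 0 else 2 * config.hidden
            lstm = BiLSTMLayer(config, din, rng, prefix=f"l{k}")
            head = CRFHead(config, 2 * config.hidden, self.tag_names, rng, prefix=f"l{k}")
            self.layers.append((lstm, head))

    @property
    def params(self) -> dict[str, Tensor]:
        out = dict(self.encoder.params)
        for lstm, head in self.layers:
            out.update(lstm.params)
            out.update(head.params)
        return out

    # -- training ---------------------------------------------------------
    def _unit_labels(self, token_labels: tuple[str, ...],
                     unit_spans: list[tuple[int, int]]) -> list[str]:
        """Project a token-level BIO row onto the current unit sequence."""
        out = []
        for a, b in unit_spans:
            window = token_labels[a:b]
            inside = [l for l in window if l != "O"]
            if not inside:
                out.append("O")
            elif len(inside) < len(window):
                logger.warning("gold mention boundary inside a merged unit; unit left O")
                out.append("O")
            else:
                out.append(window[0])
        return out

    def sentence_loss(self, sent: LevelledSentence,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Sum of per-layer CRF negative log-likelihoods for one sentence."""
        surfaces = [t.surface for t in sent.tokens]
        rep = self.encoder.encode(surfaces, rng=rng)
        unit_spans = [(i, i + 1) for i in range(len(surfaces))]
        tag_index = {t: i for i, t in enumerate(self.tag_names)}
        loss: Tensor | None = None
        current = rep
        for k in range(self.n_layers):
            lstm, head = self.layers[k]
            states = lstm.run(current)
            emissions = head.emissions(states)
            row = sent.levels[k] if k < len(sent.levels) else ("O",) * len(sent.tokens)
            unit_labels = self._unit_labels(row, unit_spans)
            tags = np.array([tag_index[l] for l in unit_labels])
            layer_loss = head.nll(emissions, tags)
            loss = layer_loss if loss is None else loss + layer_loss
            if k + 1 == self.n_layers:
                break
            if self.config.teacher_forcing:
                regions = _label_runs(unit_labels)
            else:
                path = head.decode(emissions.data)
                regions = _label_runs([self.tag_names[i] for i in path])
            if regions:
                current, unit_spans = build_next_layer_input(states, unit_spans, regions)
            else:
                current = states
        assert loss is not None
        return loss

    # -- inference ---------------------------------------------------------
    def predict(self, tokens: list[Token]) -> tuple[tuple[EntityMention, ...], LayerTrace]:
        """Decode all nesting levels of one sentence.

        Iterates encode -> CRF-decode -> merge until a layer finds nothing
        or the layer cap is reached; returns mentions with original-text
        character spans (union over layers, deduplicated on
        (span, category), earliest layer kept) plus the full trace.
        """
        trace = LayerTrace()
        if not tokens:
            return (), trace
        surfaces = [t.surface for t in tokens]
        rep = self.encoder.encode(surfaces)
        unit_spans = [(i, i + 1) for i in range(len(tokens))]
        found: dict[tuple[Span, str], EntityMention] = {}
        current = rep
        for k in range(self.n_layers):
            lstm, head = self.layers[k]
            states = lstm.run(current)
            path = head.decode(head.emissions(states).data)
            labels = [self.tag_names[i] for i in path]
            trace.unit_labels.append(labels)
            trace.unit_spans.append(list(unit_spans))
            regions = _label_runs(labels)
            if not regions:
                break  # dynamic termination: a new layer detected nothing
            for a, b, cat in regions:
                span = Span(tokens[unit_spans[a][0]].span.start,
                            tokens[unit_spans[b - 1][1] - 1].span.end)
                found.setdefault((span, cat), EntityMention(span, cat))
            current, unit_spans = build_next_layer_input(states, unit_spans, regions)
        mentions = tuple(sorted(found.values(), key=lambda m: (m.start, -len(m.span), m.category)))
        return mentions, trace

    def predict_document(self, doc_tokens: list[list[Token]]) -> tuple[EntityMention, ...]:
        out: list[EntityMention] = []
        for tokens in doc_tokens:
            mentions, _ = self.predict(tokens)
            out.extend(mentions)
        return tuple(out)


def _gold_mentions(sent: LevelledSentence) -> frozenset[EntityMention]:
    gold: set[EntityMention] = set()
    for row in sent.levels:
        gold.update(decode_bio(row, sent.tokens))
    return frozenset(gold)


def train_layered(
    train_sentences: list[LevelledSentence],
    dev_sentences: list[LevelledSentence],
    config: TaggerConfig,
    pretrained: dict[str, np.ndarray] | None = None,
) -> tuple[LayeredTagger, list[dict]]:
    """Train a layered tagger with early stopping on dev all-entities F.

    The number of layers is (max gold depth + 1) — the extra layer is
    trained on all-O targets so the stack learns to terminate — unless
    ``config.max_layers`` caps it.  Returns the best checkpoint and a
    per-epoch log of training loss and dev micro-F.
    """
    from .evaluation import strict_prf  # local import to avoid a cycle

    if not train_sentences:
        raise ValueError("empty training set")
    categories = sorted(
        {l.partition("-")[2] for s in train_sentences for row in s.levels for l in row if l != "O"}
    )
    if not categories:
        raise ValueError("training data contains no entity labels")
    depth = max(len(s.levels) for s in train_sentences)
    n_layers = depth + 1
    if config.max_layers is not None:
        n_layers = min(n_layers, config.max_layers)
    vocab = Vocabulary.build([[t.surface for t in s.tokens] for s in train_sentences])
    model = LayeredTagger(config, categories, n_layers, vocab, pretrained)
    params = model.params
    opt = Adam(params, lr=config.lr, clip=config.clip)
    rng = np.random.default_rng(config.seed + 1)
    gold_dev = [_gold_mentions(s) for s in dev_sentences]
    best_score, best_state, since_best = None, None, 0
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_sentences))
        total = 0.0
        for i in order:
            loss = model.sentence_loss(train_sentences[i], rng=rng)
            total += float(loss.data)
            loss.backward()
            opt.step()
        mean_loss = total / len(train_sentences)
        pred_dev = [set(model.predict(list(s.tokens))[0]) for s in dev_sentences]
        dev_f = strict_prf(gold_dev, pred_dev).micro.f if dev_sentences else 0.0
        log.append({"epoch": epoch, "train_loss": mean_loss, "dev_f": dev_f})
        # a dev-F tie with lower training loss still counts as progress, so a
        # small dev set saturating early does not freeze an underfit model
        score = (dev_f, -mean_loss)
        if best_score is None or score > best_score:
            best_score, since_best = score, 0
            best_state = {k: p.data.copy() for k, p in params.items()}
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    return model, log


def corpus_sentences(docs: list[AnnotatedDocument]) -> list[LevelledSentence]:
    """All levelled sentences of a document collection, in order."""
    from .nesting import document_sentences

    return [s for d in docs for s in document_sentences(d)]


def regime_sentences(docs: list[AnnotatedDocument], regime: str) -> list[LevelledSentence]:
    """Single-level sentences carrying only one regime's gold mentions —
    the training targets of the flat per-regime baselines.

    If regime filtering still leaves stacked mentions (same-span pairs),
    only level 0 is kept, with a warning.
    """
    from .nesting import document_sentences, regime_set

    out: list[LevelledSentence] = []
    for doc in docs:
        filtered = AnnotatedDocument(doc.doc_id, doc.text,
                                     tuple(regime_set(doc.mentions, regime)))
        for sent in document_sentences(filtered):
            if len(sent.levels) > 1:
                logger.warning("%s: same-span mentions in %s regime; keeping level 0",
                               doc.doc_id, regime)
            out.append(LevelledSentence(sent.tokens, sent.levels[:1]))
    return out


def split_corpus(
    docs: list[AnnotatedDocument],
    ratios: tuple[float, ...] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], ...]:
    """Document-level random split, deterministic under *seed*.

    Part sizes are the floors of ``n * ratio`` with the remainder given to
    the parts with the largest fractional shares (ties toward earlier
    parts), so a 30-document corpus at 0.8/0.1/0.1 splits 24/3/3.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(docs)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} documents into {len(ratios)} parts")
    exact = [n * r for r in ratios]
    sizes = [int(e) for e in exact]
    fracs = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in range(n - sum(sizes)):
        sizes[fracs[i % len(ratios)]] += 1
    order = np.random.default_rng(seed).permutation(n)
    parts: list[list[AnnotatedDocument]] = []
    pos = 0
    for s in sizes:
        parts.append([docs[int(i)] for i in order[pos : pos + s]])
        pos += s
    return tuple(parts)
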