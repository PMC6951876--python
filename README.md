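# phenonest

Nested named-entity recognition and concept normalization for phenotype
descriptions in biomedical text, built around the COPD (chronic obstructive
pulmonary disease) phenotype annotation scheme.

Phenotype mentions are frequently *nested*: a test-result phrase such as
*elevation of pulmonary arterial pressures* contains a measurement
(*pulmonary arterial pressures*) which itself contains an anatomical term.
In corpora annotated this way, roughly 29% of mentions are embedded inside a
longer mention. `phenonest` provides the full toolchain for working with such
corpora without requiring any external data:

- **corpus I/O** — brat-style standoff (`.txt`/`.ann`) reading, validation
  (disjoint-or-nested invariant) and writing, under a 16-category COPD
  phenotype scheme (`Problem`, `Treatment`, `Test`, `ConstituentConcept`
  hierarchies);
- **nesting** — conversion between nested mention sets and per-level BIO
  label sequences (innermost level first), and extraction of the
  *innermost* / *outermost* / *all* entity sets;
- **a layered BiLSTM-CRF tagger** — the core model: a stack of BiLSTM-CRF
  layers in which every entity detected by a layer is merged into a single
  averaged unit before the next layer runs, so entities that enclose
  already-found ones become contiguous and recognizable; stacking stops when
  a new layer finds nothing.  A single-layer instance is the flat baseline;
- **evaluation** — strict span+category matching with per-category and
  micro-averaged P/R/F per regime, inter-annotator agreement as micro-F,
  and an error taxonomy (wrong type / overlapping span / spurious / missed);
- **normalization** — six rule-based variant-generation techniques
  (abbreviation expansion, plural→singular, neoclassical↔English,
  syntactic variation, synonym substitution) matched against a pluggable
  terminology, with per-category coverage reporting;
- **a synthetic corpus generator** — deterministic, template-based nested
  corpora with a controlled embedded-mention fraction, used by the test
  suite and the examples.

## The model

For a sentence with tokens $w_1..w_T$, each token is represented by a word
embedding concatenated with the final states of a character-level BiLSTM.
A sentence-level BiLSTM produces contextual states $h_1..h_T$, scored by a
linear-chain CRF:

$$s(y) = \sum_t \big(P_{t,y_t} + A_{y_{t-1},y_t}\big),\qquad
  p(y\mid x) = \frac{e^{s(y)}}{\sum_{y'} e^{s(y')}}$$

with emission scores $P = hW$, learned transitions $A$ (invalid BIO
transitions masked), Viterbi decoding and forward-algorithm normalization.
The layered tagger applies this block repeatedly: entities decoded at layer
$k$ are collapsed to single units (element-wise average of their contextual
states) and the shortened sequence feeds layer $k+1$, until a layer decodes
nothing.  Training uses one CRF negative log-likelihood per layer with
gold lower-level regions (teacher forcing) and one extra all-outside layer
so the stack learns to terminate.

Everything runs on CPU: the networks and their gradients are implemented in
numpy via a small reverse-mode autodiff engine (`phenonest._autodiff`).

## Worked example

```python
from phenonest import (GeneratorConfig, generate_corpus, corpus_sentences,
                       split_corpus, train_layered, strict_prf, TaggerConfig)
from phenonest.layered import _gold_mentions

corpus = generate_corpus(GeneratorConfig(seed=7, n_documents=60,
                                         sentences_per_document=(3, 5)))
train, dev, test = split_corpus(list(corpus.documents), seed=7)
cfg = TaggerConfig(word_dim=24, char_dim=12, char_hidden=12, hidden=32,
                   dropout=0.25, epochs=20, patience=6, seed=7)
model, log = train_layered(corpus_sentences(train)[:200],
                           corpus_sentences(dev), cfg)
gold = [_gold_mentions(s) for s in corpus_sentences(test)]
pred = [set(model.predict(list(s.tokens))[0]) for s in corpus_sentences(test)]
print(f"test all-entities F = {strict_prf(gold, pred).micro.f:.2f}")
```

prints (deterministically, ~2 minutes on one CPU):

```
test all-entities F = 100.00
```

i.e. the layered tagger recovers every nested gold mention (exact span +
category) of the held-out documents, across both nesting levels — the
controlled generator makes the task fully learnable at this scale, which
is what makes it a useful correctness check (see `docs/methods.md` for
what this does and does not say about real corpora).
The scripts in `examples/` walk through each capability the same way —
corpus generation and statistics, BIO encoding, training and layer-by-layer
prediction, evaluation and agreement, and normalization — each printing the
numbers it computes and what they mean.

A command-line interface wraps the same functions
(`phenonest generate|train|predict|evaluate|iaa|normalize|stats`); run
`phenonest --help`.

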