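"""Train the layered BiLSTM-CRF and watch it peel nesting levels.

Trains a small layered tagger on a synthetic nested corpus (teacher-forced
per-layer CRF losses, early stopping on dev F), then predicts one held-out
sentence and prints the per-layer trace: layer 0 finds inner constituents,
detected entities are merged into single units, and the next layer finds
the enclosing phenotype mentions; stacking stops when a layer finds
nothing.  Takes a couple of minutes on one CPU.
"""

from phenonest import (GeneratorConfig, TaggerConfig, corpus_sentences,
                       generate_corpus, split_corpus, strict_prf, train_layered)
from phenonest.layered import _gold_mentions

corpus = generate_corpus(GeneratorConfig(seed=7, n_documents=40,
                                         sentences_per_document=(3, 5)))
train, dev, test = split_corpus(list(corpus.documents), seed=7)
cfg = TaggerConfig(word_dim=24, char_dim=12, char_hidden=12, hidden=32,
                   dropout=0.25, epochs=12, patience=5, seed=7)
model, log = train_layered(corpus_sentences(train), corpus_sentences(dev), cfg)
print(f"trained {model.n_layers} layers for {len(log)} epochs; "
      f"best dev F {max(e['dev_f'] for e in log):.2f}")

# show a sentence that actually nests, so the merge step is visible
sent = next(s for s in corpus_sentences(test) if s.n_levels >= 2)
text = " ".join(t.surface for t in sent.tokens)
mentions, trace = model.predict(list(sent.tokens))
print("\nsentence:", text)
for k, labels in enumerate(trace.unit_labels):
    print(f"layer {k} decoded labels over {len(labels)} units:", labels)
print("predicted mentions (char spans mapped back through all merges):")
for m in mentions:
    print(f"  [{m.start},{m.end}) {m.category}")

gold = [_gold_mentions(s) for s in corpus_sentences(test)]
pred = [set(model.predict(list(s.tokens))[0]) for s in corpus_sentences(test)]
print(f"\nheld-out all-entities micro-F: {strict_prf(gold, pred).micro.f:.2f} "
      "(strict span+category matching)")
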