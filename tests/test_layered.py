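"""Region merging, layer stacking mechanics, splits, and back-mapping."""

import numpy as np
import pytest

from phenonest._autodiff import Tensor
from phenonest.layered import (
    LayeredTagger,
    _label_runs,
    build_next_layer_input,
    corpus_sentences,
    merge_region,
    regime_sentences,
    split_corpus,
    train_layered,
)
from phenonest.nesting import document_sentences
from phenonest.synthetic import GeneratorConfig, generate_corpus
from phenonest.tagger import TaggerConfig, Vocabulary

TINY = TaggerConfig(word_dim=8, char_dim=4, char_hidden=4, hidden=6,
                    dropout=0.0, epochs=2, seed=0)


class TestMergeRegion:
    def test_single_state_returned_unchanged(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(merge_region(Tensor(v)).data, v)

    def test_two_states_average(self):
        states = Tensor(np.array([[2.0, 0.0], [0.0, 4.0]]))
        assert np.allclose(merge_region(states).data, [[1.0, 2.0]])

    def test_identical_states_idempotent(self):
        states = Tensor(np.tile([[1.5, -2.0]], (5, 1)))
        assert np.allclose(merge_region(states).data, [[1.5, -2.0]])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            merge_region(Tensor(np.zeros((0, 3))))


class TestBuildNextLayerInput:
    def test_no_regions_is_identity(self):
        states = Tensor(np.arange(12.0).reshape(4, 3))
        spans = [(0, 1), (1, 2), (2, 3), (3, 4)]
        out, new_spans = build_next_layer_input(states, spans, [])
        assert np.allclose(out.data, states.data)
        assert new_spans == spans

    def test_two_unit_region_shortens_by_one(self):
        states = Tensor(np.arange(8.0).reshape(4, 2))
        spans = [(0, 1), (1, 2), (2, 3), (3, 4)]
        out, new_spans = build_next_layer_input(states, spans, [(1, 3, "Drug")])
        assert out.shape == (3, 2)
        assert new_spans == [(0, 1), (1, 3), (3, 4)]
        assert np.allclose(out.data[1], states.data[1:3].mean(axis=0))

    def test_full_cover_region_collapses_to_one_unit(self):
        states = Tensor(np.arange(10.0).reshape(5, 2))
        spans = [(i, i + 1) for i in range(5)]
        out, new_spans = build_next_layer_input(states, spans, [(0, 5, "Treatment")])
        assert out.shape == (1, 2)
        assert new_spans == [(0, 5)]

    def test_spans_compose_across_two_collapses(self):
        states = Tensor(np.zeros((5, 2)))
        spans = [(i, i + 1) for i in range(5)]
        out, spans2 = build_next_layer_input(states, spans, [(1, 3, "Drug")])
        _, spans3 = build_next_layer_input(out, spans2, [(0, 2, "Treatment")])
        assert spans3 == [(0, 3), (3, 4), (4, 5)]


class TestLabelRuns:
    @pytest.mark.parametrize(
        "labels, runs",
        [
            (["O", "O"], []),
            (["B-X", "I-X", "O"], [(0, 2, "X")]),
            (["O", "I-X"], [(1, 2, "X")]),                      # repair
            (["B-X", "I-Y"], [(0, 1, "X"), (1, 2, "Y")]),       # category switch
            (["B-X", "B-X"], [(0, 1, "X"), (1, 2, "X")]),
        ],
    )
    def test_run_extraction_with_repair(self, labels, runs):
        assert _label_runs(labels) == runs


class TestSplitCorpus:
    def test_30_docs_split_24_3_3(self):
        docs = list(generate_corpus(GeneratorConfig(seed=0, n_documents=30)).documents)
        tr, dv, te = split_corpus(docs, seed=1)
        assert (len(tr), len(dv), len(te)) == (24, 3, 3)

    def test_partition_is_disjoint_and_complete(self):
        docs = list(generate_corpus(GeneratorConfig(seed=0, n_documents=17)).documents)
        parts = split_corpus(docs, seed=5)
        ids = [d.doc_id for p in parts for d in p]
        assert sorted(ids) == sorted(d.doc_id for d in docs)
        assert len(set(ids)) == len(ids)

    def test_deterministic_under_seed(self):
        docs = list(generate_corpus(GeneratorConfig(seed=0, n_documents=12)).documents)
        a = split_corpus(docs, seed=9)
        b = split_corpus(docs, seed=9)
        assert [[d.doc_id for d in p] for p in a] == [[d.doc_id for d in p] for p in b]

    def test_fewer_docs_than_parts_raises(self):
        docs = list(generate_corpus(GeneratorConfig(seed=0, n_documents=2)).documents)
        with pytest.raises(ValueError):
            split_corpus(docs, ratios=(0.4, 0.3, 0.3), seed=0)

    def test_bad_ratios_raise(self):
        docs = list(generate_corpus(GeneratorConfig(seed=0, n_documents=5)).documents)
        with pytest.raises(ValueError):
            split_corpus(docs, ratios=(0.5, 0.2), seed=0)


@pytest.fixture(scope="module")
def toy_model():
    """A briefly trained 2-level model shared by the inference tests."""
    corpus = generate_corpus(GeneratorConfig(seed=3, n_documents=20))
    sents = corpus_sentences(list(corpus.documents))
    cfg = TaggerConfig(word_dim=12, char_dim=6, char_hidden=6, hidden=16,
                       dropout=0.0, epochs=6, patience=6, seed=3)
    model, log = train_layered(sents[:80], sents[80:95], cfg)
    return model, corpus


class TestLayeredTagger:
    def test_needs_at_least_one_layer(self):
        vocab = Vocabulary.build([["x"]])
        with pytest.raises(ValueError):
            LayeredTagger(TINY, ["Drug"], 0, vocab)

    def test_empty_token_list_gives_empty_output(self, toy_model):
        model, _ = toy_model
        mentions, trace = model.predict([])
        assert mentions == ()
        assert trace.n_layers == 0

    def test_terminates_within_layer_cap(self, toy_model):
        model, corpus = toy_model
        for doc in corpus.documents[:6]:
            for sent in document_sentences(doc):
                _, trace = model.predict(list(sent.tokens))
                assert trace.n_layers <= model.n_layers

    def test_unit_counts_monotonically_shrink(self, toy_model):
        model, corpus = toy_model
        for doc in corpus.documents[:6]:
            for sent in document_sentences(doc):
                _, trace = model.predict(list(sent.tokens))
                lengths = [len(u) for u in trace.unit_spans]
                assert all(b <= a for a, b in zip(lengths, lengths[1:]))

    def test_predicted_spans_align_with_token_boundaries(self, toy_model):
        """Back-mapping soundness: every predicted span is a whole-token span."""
        model, corpus = toy_model
        for doc in corpus.documents[:8]:
            for sent in document_sentences(doc):
                mentions, _ = model.predict(list(sent.tokens))
                starts = {t.span.start for t in sent.tokens}
                ends = {t.span.end for t in sent.tokens}
                for m in mentions:
                    assert m.start in starts and m.end in ends

    def test_prediction_deterministic(self, toy_model):
        model, corpus = toy_model
        sent = document_sentences(corpus.documents[0])[0]
        a, _ = model.predict(list(sent.tokens))
        b, _ = model.predict(list(sent.tokens))
        assert a == b

    def test_max_layers_one_cannot_reach_nested_levels(self):
        """Flat ablation on nested data: only one layer of predictions."""
        corpus = generate_corpus(GeneratorConfig(seed=6, n_documents=12, p_nest=1.0))
        sents = corpus_sentences(list(corpus.documents))
        cfg = TaggerConfig(word_dim=12, char_dim=6, char_hidden=6, hidden=16,
                           dropout=0.0, epochs=3, patience=3, seed=6, max_layers=1)
        model, _ = train_layered(sents[:40], sents[40:50], cfg)
        assert model.n_layers == 1
        for sent in sents[50:60]:
            _, trace = model.predict(list(sent.tokens))
            assert trace.n_layers <= 1


class TestTrainLayered:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_layered([], [], TINY)

    def test_loss_decreases_on_repeated_sentence(self):
        corpus = generate_corpus(GeneratorConfig(seed=9, n_documents=2))
        sent = next(s for s in corpus_sentences(list(corpus.documents)) if s.n_levels >= 2)
        cfg = TaggerConfig(word_dim=8, char_dim=4, char_hidden=4, hidden=8,
                           dropout=0.0, epochs=25, patience=25, lr=1e-2, seed=9)
        _, log = train_layered([sent] * 4, [sent], cfg)
        losses = [e["train_loss"] for e in log]
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.5

    def test_layer_count_covers_training_depth_plus_termination(self, toy_model):
        model, corpus = toy_model
        max_depth = max(max(l.values(), default=0) for l in corpus.levels) + 1
        assert model.n_layers == max_depth + 1


class TestRegimeSentences:
    def test_outermost_sentences_are_single_level(self, small_corpus):
        sents = regime_sentences(list(small_corpus.documents), "outermost")
        assert all(s.n_levels == 1 for s in sents)

    def test_regime_sentences_keep_only_regime_mentions(self, small_corpus):
        from phenonest.nesting import decode_bio, regime_set

        docs = list(small_corpus.documents)
        sents = regime_sentences(docs, "innermost")
        decoded = set()
        for s in sents:
            decoded.update(decode_bio(s.levels[0], s.tokens))
        expected = set()
        for d in docs:
            expected.update(regime_set(d.mentions, "innermost"))
        assert decoded == expected
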