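"""Level assignment, BIO encode/decode round trips, and regime sets."""

import pytest
from hypothesis import given, settings, strategies as st

from phenonest.nesting import (
    NestingInvariantError,
    assign_levels,
    decode_bio,
    document_sentences,
    encode_bio,
    innermost_set,
    outermost_set,
    regime_set,
    to_column_format,
    tokenize,
)
from phenonest.standoff import EntityMention, Span, validate_mentions


def mention(start, end, cat="Condition"):
    return EntityMention(Span(start, end), cat)


@st.composite
def nested_mention_sets(draw):
    """Random disjoint-or-nested mention sets over a 60-char span."""
    cats = ("Condition", "Drug", "Treatment", "Test", "Quality")
    n = draw(st.integers(1, 10))
    raw = [
        mention(s, s + l, draw(st.sampled_from(cats)))
        for s, l in zip(
            draw(st.lists(st.integers(0, 50), min_size=n, max_size=n)),
            draw(st.lists(st.integers(1, 10), min_size=n, max_size=n)),
        )
    ]
    return list(validate_mentions(raw, 60, policy="drop"))


class TestTokenize:
    def test_offsets_and_compound_tokens(self):
        toks = tokenize("reduced FEV1, alpha1-antitrypsin .")
        assert [t.surface for t in toks] == ["reduced", "FEV1", ",", "alpha1-antitrypsin", "."]
        assert all(t.surface == "reduced FEV1, alpha1-antitrypsin ."[t.span.start:t.span.end]
                   for t in toks)


class TestAssignLevels:
    def test_nested_pair_orders_innermost_first(self):
        inner = mention(13, 31, "AnatomicalConcept")
        outer = mention(0, 41, "TestResult")
        levels = assign_levels([inner, outer])
        assert levels[inner] == 0
        assert levels[outer] >= 1

    def test_single_mention_is_level_zero(self):
        m = mention(0, 7)
        assert assign_levels([m]) == {m: 0}

    def test_same_span_categories_stack_lexicographically(self):
        d, t = mention(0, 4, "Drug"), mention(0, 4, "Treatment")
        levels = assign_levels([d, t])
        assert levels[d] == 0 and levels[t] == 1

    def test_crossing_overlap_rejected(self):
        with pytest.raises(NestingInvariantError):
            assign_levels([mention(0, 5), mention(3, 8, "Drug")])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(nested_mention_sets())
    def test_containment_ordering_matches_brute_force(self, mentions):
        levels = assign_levels(mentions)
        for a in mentions:
            for b in mentions:
                if a.span.contains(b.span):
                    assert levels[a] > levels[b]
        # mentions on one level are pairwise disjoint
        for a in mentions:
            for b in mentions:
                if a != b and levels[a] == levels[b]:
                    assert not a.span.overlaps(b.span)


class TestBioCoding:
    def test_single_token_mention(self):
        toks = tokenize("dyspnea")
        sent = encode_bio(toks, [mention(0, 7, "SignOrSymptom")])
        assert sent.levels == (("B-SignOrSymptom",),)

    def test_no_mentions_single_all_o_level(self):
        sent = encode_bio(tokenize("plain text here"), [])
        assert sent.levels == (("O", "O", "O"),)

    def test_drug_inside_treatment_two_levels(self):
        text = "inhaled corticosteroids ."
        toks = tokenize(text)
        ms = [mention(8, 23, "Drug"), mention(0, 23, "Treatment")]
        sent = encode_bio(toks, ms)
        assert sent.levels[0] == ("O", "B-Drug", "O")
        assert sent.levels[1] == ("B-Treatment", "I-Treatment", "O")

    def test_decode_all_o_is_empty(self):
        assert decode_bio(["O", "O", "O"], tokenize("a b c")) == ()

    def test_decode_b_i_run(self):
        toks = tokenize("inhaled corticosteroids .")
        got = decode_bio(["B-Drug", "I-Drug", "O"], toks)
        assert got == (mention(0, 23, "Drug"),)

    def test_orphan_i_repaired_as_b(self):
        toks = tokenize("a corticosteroids")
        got = decode_bio(["O", "I-Drug"], toks)
        assert got == (mention(2, 17, "Drug"),)

    def test_mid_token_boundary_snaps_outward(self):
        toks = tokenize("corticosteroids")
        sent = encode_bio(toks, [mention(0, 6, "Drug")])  # boundary inside token
        assert sent.levels[0] == ("B-Drug",)

    def test_bioes_encoding_round_trips(self):
        toks = tokenize("inhaled corticosteroids now")
        ms = [mention(0, 23, "Treatment"), mention(24, 27, "Quality")]
        sent = encode_bio(toks, ms, scheme_tag="BIOES")
        assert sent.levels[0] == ("B-Treatment", "E-Treatment", "S-Quality")
        assert set(decode_bio(sent.levels[0], toks)) == set(ms)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(nested_mention_sets())
    def test_encode_decode_round_trip_per_level(self, mentions):
        text = "x" * 60
        toks = tokenize(" ".join(["ab"] * 20))  # 20 tokens covering offsets 0..59
        snapped = []
        # pre-snap mentions to token boundaries so the round trip is exact
        for m in mentions:
            cover = [t for t in toks if t.span.overlaps(m.span)]
            if not cover:
                continue
            snapped.append(EntityMention(Span(cover[0].span.start, cover[-1].span.end), m.category))
        snapped = list(validate_mentions(snapped, 60, policy="drop"))
        assignment = assign_levels(snapped)
        sent = encode_bio(toks, snapped, assignment)
        decoded = set()
        for row in sent.levels:
            decoded.update(decode_bio(row, toks))
        assert decoded == set(snapped)


class TestRegimeSets:
    def test_nested_pair(self):
        a, b = mention(0, 10, "Treatment"), mention(2, 6, "Drug")
        assert innermost_set([a, b]) == {b}
        assert outermost_set([a, b]) == {a}

    def test_singleton_in_both_sets(self):
        c = mention(0, 7, "SignOrSymptom")
        assert innermost_set([c]) == {c} == outermost_set([c])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(nested_mention_sets())
    def test_matches_brute_force_containment(self, mentions):
        inner = {
            m for m in mentions
            if not any(m.span.contains(o.span) for o in mentions)
        }
        outer = {
            m for m in mentions
            if not any(o.span.contains(m.span) for o in mentions)
        }
        assert regime_set(mentions, "innermost") == inner
        assert regime_set(mentions, "outermost") == outer
        assert regime_set(mentions, "all") == set(mentions)
        assert inner | outer <= set(mentions)

    def test_nesting_free_document_regimes_coincide(self):
        ms = [mention(0, 3), mention(5, 9, "Drug")]
        assert innermost_set(ms) == outermost_set(ms) == set(ms)


class TestColumnExport:
    def test_column_format_shape(self, small_corpus):
        doc = small_corpus.documents[0]
        sents = document_sentences(doc)
        text = to_column_format(sents)
        blocks = text.strip().split("\n\n")
        assert len(blocks) == len(sents)
        for block, sent in zip(blocks, sents):
            lines = block.splitlines()
            assert len(lines) == len(sent.tokens)
            assert all(len(l.split("\t")) == 1 + max(sent.n_levels, 1) for l in lines)
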