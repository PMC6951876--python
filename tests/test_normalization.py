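"""Variant generation, terminology matching, and coverage arithmetic."""

import pytest

from phenonest.normalization import (
    ConceptEntry,
    Terminology,
    coverage_from_counts,
    coverage_report,
    default_rules,
    default_terminology,
    generate_variants,
    normalize_mention,
)
from phenonest.scheme import SchemeError, copd_scheme


@pytest.fixture(scope="module")
def rules():
    return default_rules()


@pytest.fixture(scope="module")
def terminology():
    return default_terminology()


class TestGenerateVariants:
    def test_original_mention_comes_first(self, rules):
        assert generate_variants("lung failure", rules)[0] == "lung failure"

    @pytest.mark.parametrize(
        "mention, expected_variant",
        [
            ("Type 2 DM", "type 2 diabetes mellitus"),            # abbreviation expansion
            ("alveolar septa", "alveolar septum"),                 # plural -> singular
            ("elevated blood leukocyte counts",
             "elevated white blood cell count"),                   # neoclassical -> English (+ plural)
            ("pleural inflammation", "pleuritis"),                 # English -> neoclassical
            ("supplemental oxygen", "oxygen supplementation"),     # syntactic variation
            ("worsening pulmonary function",
             "deterioration of lung function"),                    # synonym (+ neoclassical)
        ],
    )
    def test_six_technique_examples(self, rules, mention, expected_variant):
        assert expected_variant in generate_variants(mention, rules)

    def test_no_applicable_rule_gives_singleton(self, rules):
        assert generate_variants("xyzzy", rules) == ["xyzzy"]

    def test_deterministic_and_duplicate_free(self, rules):
        a = generate_variants("worsening pulmonary function", rules)
        b = generate_variants("worsening pulmonary function", rules)
        assert a == b
        assert len(a) == len(set(a))

    def test_breadth_cap_respected(self, rules):
        assert len(generate_variants("elevated blood leukocyte counts", rules,
                                     max_variants=5)) <= 5


class TestNormalizeMention:
    @pytest.mark.parametrize(
        "mention, category, concept",
        [
            ("increased PVR", "Problem", "C1867423"),
            ("lung failure", "Condition", "C0948755"),
            ("left atrial", "AnatomicalConcept", "C0225860"),
            ("arm training", "Treatment", "C0556501"),
            ("spirometric test", "TestOrMeasure", "C0037981"),
            ("genetic predisposition", "RiskFactor", "C1455997"),
        ],
    )
    def test_sample_mappings(self, terminology, rules, mention, category, concept):
        res = normalize_mention(mention, category, terminology, rules, scheme=copd_scheme())
        assert res.concept_id == concept

    def test_preferred_label_is_direct_match_with_empty_trail(self, terminology, rules):
        res = normalize_mention("Pulmonary failure", "Condition", terminology, rules)
        assert res.concept_id == "C0948755"
        assert res.trail == ()

    def test_unmappable_mention_stays_unnormalized(self, terminology, rules):
        res = normalize_mention("negative pleural pressure", "TestResult", terminology, rules)
        assert res.concept_id is None
        assert not res.normalized

    def test_multi_concept_mention_fails_to_normalize(self, terminology, rules):
        res = normalize_mention(
            "coughing and/or corticosteroid-induced osteoporosis",
            "SignOrSymptom", terminology, rules,
        )
        assert res.concept_id is None

    def test_category_filter_blocks_cross_category_match(self, terminology, rules):
        # the surface exists, but only under Condition-tagged concepts
        res = normalize_mention("lung failure", "Treatment", terminology, rules)
        assert res.concept_id is None

    def test_unknown_category_is_scheme_error(self, terminology, rules):
        with pytest.raises(SchemeError):
            normalize_mention("cough", "NotACategory", terminology, rules, scheme=copd_scheme())

    def test_matched_identifier_always_in_terminology(self, terminology, rules):
        for mention, cat in [("increased PVR", "Problem"), ("emphysema", "Condition"),
                             ("shortness of breath", "SignOrSymptom")]:
            res = normalize_mention(mention, cat, terminology, rules)
            if res.concept_id is not None:
                assert res.concept_id in terminology

    def test_enlarging_terminology_never_loses_matches(self, terminology, rules):
        mentions = [("increased PVR", "Problem"), ("negative pleural pressure", "TestResult"),
                    ("lung failure", "Condition")]
        before = sum(
            normalize_mention(m, c, terminology, rules).normalized for m, c in mentions
        )
        bigger = Terminology(
            list(terminology.entries.values())
            + [ConceptEntry("C9990001", "Negative pleural pressure", (), frozenset({"TestResult"}))]
        )
        after = sum(
            normalize_mention(m, c, bigger, rules).normalized for m, c in mentions
        )
        assert after >= before
        assert after == before + 1


class TestCoverage:
    def test_percentages_recompute_from_counts(self):
        report = coverage_from_counts({"Condition": (5119, 4969), "Protein": (820, 727)})
        by_cat = report.as_dict()
        assert by_cat["Condition"]["percentage"] == 97.07
        assert by_cat["Protein"]["percentage"] == 88.66
        total = report.total_row
        assert total.total == 5939 and total.normalized == 5696

    def test_zero_total_category_flagged(self):
        report = coverage_from_counts({"Quality": (0, 0)})
        row = report.rows[0]
        assert row.percentage == 0.0
        assert not row.defined

    def test_report_from_results_counts_by_category(self, terminology, rules):
        results = [
            normalize_mention("lung failure", "Condition", terminology, rules),
            normalize_mention("no such concept xq", "Condition", terminology, rules),
            normalize_mention("increased PVR", "Problem", terminology, rules),
        ]
        report = coverage_report(results)
        d = report.as_dict()
        assert d["Condition"] == {"total": 2, "normalized": 1, "percentage": 50.0}
        assert d["Problem"]["normalized"] == 1
        assert d["Total"]["total"] == 3
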