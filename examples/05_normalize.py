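"""Rule-based normalization of mentions to terminology concepts.

Generates string variants of each mention with the six techniques
(abbreviation expansion, plural→singular, neoclassical↔English,
syntactic variation, synonym substitution), matches them against the
packaged mock terminology filtered by semantic category, and prints the
matched concept and the technique trail that produced the winning
variant.  Ends with a per-category coverage table.
"""

from phenonest import (coverage_report, default_rules, default_terminology,
                       generate_variants, normalize_mention)
from phenonest.scheme import copd_scheme

rules = default_rules()
terminology = default_terminology()
scheme = copd_scheme()

print("variants of 'worsening pulmonary function':")
for v in generate_variants("worsening pulmonary function", rules)[:8]:
    print("  ", v)

mentions = [
    ("increased PVR", "Problem"),
    ("lung failure", "Condition"),
    ("left atrial", "AnatomicalConcept"),
    ("arm training", "Treatment"),
    ("spirometric test", "TestOrMeasure"),      # alias of the Test category
    ("genetic predisposition", "RiskFactor"),
    ("negative pleural pressure", "TestResult"),  # no concept: stays unnormalized
]
print("\nnormalization results:")
results = []
for mention, category in mentions:
    res = normalize_mention(mention, category, terminology, rules, scheme)
    results.append(res)
    concept = res.concept_id or "(unnormalized)"
    label = terminology.entries[res.concept_id].preferred if res.concept_id else "-"
    if res.concept_id is None:
        trail = "-"
    else:
        trail = " -> ".join(res.trail) if res.trail else "direct"
    print(f"  {mention!r:40s} {concept:14s} {label:40s} via {trail}")

print("\ncoverage by category (share of mentions linked to a concept):")
print(coverage_report(results).to_table())
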