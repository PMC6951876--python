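"""Nested mentions as per-level BIO label sequences.

Encodes a sentence with a drug nested inside a treatment into one BIO row
per nesting level (level 0 = innermost), shows the column export used for
sequence-labeling interoperability, and decodes the rows back to spans.
"""

from phenonest import (EntityMention, Span, assign_levels, decode_bio, encode_bio,
                       innermost_set, outermost_set, tokenize)
from phenonest.nesting import to_column_format

text = "inhaled corticosteroids reduce chronic cough ."
tokens = tokenize(text)
mentions = [
    EntityMention(Span(8, 23), "Drug"),           # corticosteroids
    EntityMention(Span(0, 23), "Treatment"),      # inhaled corticosteroids
    EntityMention(Span(31, 44), "SignOrSymptom"), # chronic cough
]

levels = assign_levels(mentions)
print("levels (0 = innermost):", {f"{text[m.start:m.end]}": l for m, l in levels.items()})

sent = encode_bio(tokens, mentions, levels)
print("\ncolumn format (token, one BIO column per level):")
print(to_column_format([sent]))

for k, row in enumerate(sent.levels):
    decoded = decode_bio(row, tokens)
    print(f"level {k} decodes to:", [(text[m.start:m.end], m.category) for m in decoded])

print("\ninnermost set:", sorted(text[m.start:m.end] for m in innermost_set(mentions)))
print("outermost set:", sorted(text[m.start:m.end] for m in outermost_set(mentions)))
print("(the non-nested sign/symptom appears in both sets)")
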