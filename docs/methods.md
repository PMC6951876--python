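# Methods

This note documents the models and procedures implemented in `phenonest`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Nested annotation model

A document is text plus a set of typed character spans (0-based, half-open,
over Unicode code points; no convention is universal for standoff data, so
this one is fixed and enforced on read).  After validation, any two spans
are disjoint, identical with different categories, or properly nested.
Crossing overlaps cannot be represented in a per-level label encoding; the
default policy drops the later-starting mention with a warning, and a
strict mode raises instead.  Identical (span, category) duplicates are
removed; identical spans with different categories are kept and occupy
consecutive nesting levels in lexicographic category order — the layering
of same-span multi-category annotations is underdetermined in standoff
data, so a deterministic convention is used and logged.

Nesting levels are innermost-first: a mention's level is the length of the
longest chain of mentions strictly contained in it, so level 0 feeds the
first model layer and a 3-deep nest occupies 3 levels.  Each level is a
BIO sequence over tokens (BIOES available behind a flag; BIO is the
default because sparse categories make the richer scheme data-hungry).
Mention boundaries that fall inside a token snap outward to token
boundaries, preserving recall at the cost of slightly widened spans; every
snap is logged.  Tokenization is whitespace/punctuation splitting with
offset preservation; alphanumeric tokens such as `FEV1` and hyphenated
compounds are kept whole.  The *innermost* set contains mentions that
contain no other mention, the *outermost* set those contained in no other;
nesting-free mentions belong to both.

## Flat BiLSTM-CRF block

Token representation: a word embedding (lookup on the lowercased surface,
learned unknown vector) concatenated with the two final states of a
character-level BiLSTM over the case-preserved surface.  A sentence-level
BiLSTM yields contextual states; a linear projection gives per-tag emission
scores; a linear-chain CRF with learned transition and boundary potentials
scores label paths.  Transitions that would produce malformed BIO output
(`O→I-x`, `B-x→I-y`, start at `I-x`) carry a large additive penalty
(−10⁴, kept finite for numerical safety) by default, since strict
evaluation punishes malformed spans; decoding therefore always produces
well-formed label sequences, and a conventional BIO repair (orphan `I`
read as `B`) makes decoding total for unmasked configurations.

Defaults: word dim 100, char embedding 25 and char hidden 25 per
direction, sentence hidden 200 per direction, dropout 0.5 on the combined
representation.  All are config-overridable; no hyperparameter search is
performed.  Optimization is per-sentence Adam (lr 5·10⁻³, global-norm
gradient clipping at 5) with early stopping on development micro-F.  An
epoch that ties the best development F with a lower training loss counts
as progress for the patience counter: with small development sets the
dev score saturates many epochs before the model stops improving, and
freezing at first saturation returns an underfit model.  Every source of
randomness (initialization, shuffling, dropout) flows from one seed;
evaluation mode is fully deterministic.

The networks are implemented in numpy with a purpose-built reverse-mode
autodiff engine; gradient correctness is tested against finite differences
through the whole embeddings→BiLSTM→CRF graph, and the CRF loss against an
independent numpy implementation whose partition function and decoder are
themselves tested against exhaustive path enumeration.

## Layered tagger

The layered model applies the flat block repeatedly.  Layer 0 reads token
representations; every entity decoded by layer *k* is collapsed into one
unit whose vector is the element-wise average of its units' contextual
states (averaging is order-robust and dimension-preserving; the merge
function is otherwise unconstrained, and averaging follows the established
layered-model lineage), non-entity units pass through, and the shortened
sequence feeds layer *k*+1.  Prediction iterates until a newly applied
layer decodes nothing or the layer cap is reached; the output is the union
over layers of all decoded mentions mapped back to original character
spans (unit→token ranges compose across collapses), deduplicated on
(span, category) keeping the earliest layer's instance.

Training builds each layer's input from *gold* lower-level regions
(teacher forcing) by default — the objective is then deterministic and
stable — with a config flag to use model-predicted regions instead; which
regime the original layered models used end-to-end is not documented, so
both are available and neither is presented as canonical.  The loss is the
sum of per-layer CRF negative log-likelihoods.  The number of trained
layers is the maximum gold nesting depth plus one: the extra layer is
trained on all-outside targets, which is what teaches the stack to
terminate.  Per-layer parameters are independent by default (layers 1+ can
share weights behind a flag; layer 0 is always separate because its input
dimension differs).

Model layers do not correspond one-to-one to nesting levels at prediction
time — a layer may recover entities of any depth.  Per-regime evaluation
of the layered model therefore uses the union of all layers' outputs
filtered by regime membership *within the model's own predicted nesting
structure*, never "layer k versus level k".  Flat baselines are instead
trained per regime (e.g. on outermost labels only) and evaluated directly.

## Evaluation

Strict matching: a prediction is correct iff its span and category both
match a gold mention.  Reports carry per-category and micro-averaged
P/R/F (percentages, rendered to 2 decimals) with the underlying TP/FP/FN
counts; precision over an empty prediction set is reported as 0 and
flagged.  Inter-annotator agreement is the micro-F of one annotator
scored against the other; micro-F is symmetric under swapping roles.
Each annotated mention is counted once (not once per level).

The error taxonomy uses greedy one-to-one matching — exact matches, then
same-span/different-category pairs, then same-category overlapping pairs
by decreasing overlap (earliest start on ties), remainder spurious/missed
— so every false positive and false negative lands in exactly one bucket;
the matcher itself is a convention, as error-taxonomy matchers generally
are.

## Normalization

Six variant-generation techniques run in a fixed order (abbreviation
expansion; plural→singular; neoclassical→English; English→neoclassical;
syntactic variation; synonym substitution), composing to depth 2 with a
breadth cap of 200 — the original pipeline's internal ordering and
composition limits are unpublished, so these are package conventions.
The original mention always comes first and the first variant with a hit
in the category-filtered terminology wins, so results and technique
trails are deterministic.  Matching is case-insensitive after whitespace
folding.  Mentions describing several concepts at once are not split and
simply fail to normalize.  The packaged terminology is a small synthetic
mock (clearly marked as such); real dictionaries plug in through the same
TSV format, and enlarging the terminology can only increase the
normalized count.  Coverage reports recompute every percentage from their
own counts; the packaged COPD-corpus count table reproduces the published
per-category totals, and the two published percentage cells that
disagree with their own printed counts by exactly 1.00 (Problem, Protein)
are reported as the arithmetic dictates (84.15, 88.66).

## Synthetic data

The generator emits template-based sentences: distractor words interleaved
with entity groups; a group is either a flat one-token mention or, with
probability `p_nest`, a nested chain (anatomical phrase inside a
condition, drug phrase inside a treatment, test phrase inside a test
result; chains deepen with probability `p_nest` per level up to
`max_depth`).  The default `p_nest = 0.41` with `max_depth = 2` puts the
expected embedded-mention fraction at 0.41/1.41 ≈ 0.29, mirroring the
share of embedded mentions reported for real phenotype corpora.

Two design points matter for what the experiments mean.  First, modifier
(quality) words also occur as plain unannotated context, and whether a
modifier opens a phenotype span depends on the constituent that follows
it — so outer-boundary decisions genuinely require recognizing inner
constituents, which is the mechanism layered stacking exists to exploit;
with outer spans that are a trivial function of adjacent tokens, a flat
model saturates and the comparison is uninformative.  The annotation rule
is kept consistent (a modifier adjacent to a phenotype phrase is always
part of it; a quality word is never the last word before a group), so
there is no label noise.  Second, consecutive entity groups are always
separated by at least one plain word, as in running prose; gold
boundaries are therefore unambiguous.  Vocabulary defaults read like the
COPD domain purely for cosmetics.

What passing desk-scale tests shows: the training objective, layer
stacking, back-mapping and evaluation machinery are correct, and nesting
information measurably helps outermost recognition under conditions where
it carries information.  What it does not show: performance on real
corpora — real phenotype mentions are far more lexically diverse,
annotations are imperfect, and boundaries are genuinely ambiguous; F
scores here (≈95–100 at 200 training sentences) are properties of the
controlled generator, not predictions for real data.

The annotator-pair generator perturbs a gold corpus (seeded drop /
relabel / one-token span-shift operations; shifts that would break
validity are skipped) to exercise agreement and error-taxonomy code with
known ground truth.

## Problem sizes and numerical choices

Desk-scale runs (test suite and acceptance script) use word 24 / char 12 /
hidden 32, 200 training sentences, ≤20 epochs — chosen so a full
train/evaluate cycle takes tens of seconds on one CPU while remaining
comfortably above the learnability threshold; the comparison runs use
three seeds.  CRF computations are in log space throughout; Viterbi ties
break toward the lowest tag index at the latest divergent step.  The
corpus split is document-level 8:1:1 (floors plus largest-remainder), so
30 documents split 24/3/3, deterministic under its seed.

## Known limitations

- No discontinuous mentions, relation/event annotations, or UIMA
  interchange; crossing overlaps are dropped, not modeled.
- The flat-vs-layered comparison is a soft, seed-averaged check by nature;
  single seeds can go either way on small corpora.
- The normalization rule tables are small, hand-curated, and English-only;
  numeric-value interpretation (e.g. mapping "oxygen saturation level
  90%") is out of scope.
- No transformer or contextual-embedding variants; CPU-only by design.
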