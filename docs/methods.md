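# Methods

`fhx` extracts two entity types from free-text family-history (FH)
notes: **Observations** (diseases/conditions attributed to a relative)
and **FamilyMembers** (normalized `(relative, side-of-family)` pairs).
Outputs are document-level *sets* — a disease mentioned five times in
one note is one annotation. This note describes the models, the
conventions they rely on, and what the synthetic benchmark does and
does not demonstrate.

## Document model and segmentation

A note is segmented into paragraphs (blank-line separated blocks),
sentences and tokens, all carrying 0-based half-open character offsets
that slice exactly back to their surface strings. The segmenter is rule
based — boundary after `.?!` + whitespace + capital, with an
abbreviation escape list (`Mrs.`, `Dr.`, …); tokens are alphanumeric
runs, apostrophe clitics (`mother's` → `mother` + `'s`) and single
punctuation marks — so segmentation is deterministic and idempotent,
which every downstream offset computation depends on. Sentence bigrams
(each sentence paired with its predecessor) provide cross-sentence
context; by default the window crosses paragraph boundaries
(`segmenter.bigrams_cross_paragraphs`), since nothing in the task
restricts context to a paragraph.

## Observation tagging: linear-chain CRF

Tagging uses the BIO schema over the alphabet
`{O, B-Observation, I-Observation}`. A sentence with emission scores
`P ∈ R^{n×T}` and tag sequence `y` scores

    score(y) = start[y_1] + Σ_i P[i, y_i] + Σ_i A[y_i, y_{i+1}] + stop[y_n]

with transition matrix `A`; `p(y|x) = exp(score(y)) / Z` where the
partition function `Z` is computed exactly by the forward recursion in
log space. Decoding is Viterbi with BIO-invalid moves (`start→I`,
`O→I`) masked to −10³⁰ (a finite stand-in for −∞ that keeps arithmetic
NaN-free); ties resolve to the lexicographically smallest tag-index
sequence via a backward best-suffix pass followed by greedy left-to-
right selection. Since `O` has index 0, ties prefer the empty
annotation.

Emissions come from a pluggable encoder. The default `LexiconEncoder`
is a sparse linear scorer over lexical features: lowercased word
identity, 2–4 character prefixes/suffixes, word shape, a ±2 token
window with a left-bigram feature, and an optional in-disease-lexicon
flag. The ±2 window is deliberate: a ±1 window cannot distinguish
`died of asthma` from `no known family history of asthma` — both put
`of` immediately left of the disease — while `w-2` (`died` vs
`history`) separates them. Unseen features score 0, so an untrained
model decodes everything as `O`.

Training maximizes the conditional log-likelihood by mini-batch
gradient ascent (defaults: learning rate 0.2, batch 8, 15 epochs, L2
10⁻⁴, fixed seed). The gradient is exact: gold indicator minus
posterior marginal, with marginals from forward–backward; it is
verified against central finite differences in the tests. When a dev
split is given (by convention the sentences of the first 18 training
documents), the per-epoch snapshot with the best span-level F1 is
returned.

Gold BIO tags are not part of the annotation format; they are
*recreated* by case-insensitive string matching of the document-level
gold strings at token boundaries, longest string first, every
occurrence tagged. Gold strings absent from the text (a known artifact
of shared-task gold) produce a warning, not an error.

**Auxiliary pretraining.** `pretrain_then_finetune` trains the tagger
on an auxiliary disease-NER corpus with the same tag alphabet, then
continues gradient ascent from those weights on the target corpus —
the intermediate-task-pretraining recipe, at the scale of this
encoder. It pays off exactly when the auxiliary corpus covers
vocabulary the small target corpus lacks; the acceptance script
measures this with disjoint disease pools.

A longest-match dictionary tagger over the bundled lexicon serves as
the untrained baseline.

## FamilyMember annotation: candidate graph + rules

Candidate mentions are occurrences of relationship words (with plural
and informal variants) from the 15-type task set; the default
configuration restricts to 11 types, dropping *child*, *sibling*,
*parent*, *grandparent*, whose surface words usually introduce nobody
in particular ("She has 4 siblings: two brothers and two sisters").

Within a sentence, adjacent candidate pairs (no intervening candidate)
are linked by the patterns `X's *Y`, `X *has/had *Y`, `Y of *X`, each
adding a directed edge X→Y ("Y is a relative of X"); wildcards span at
most 6 non-candidate tokens (`fm.wildcard_max_tokens`; the cap keeps
"mother ... had ... a sister" matches local). A coreference hook may
supply links from a referring expression to a previous-sentence
candidate, in which case the antecedent takes the X slot; no
coreference model is bundled — the best configuration runs without
one, because sentence-pair coreference resolves grammatically
plausible but annotation-hostile readings ("Her brother…" after "The
patient's mother…").

Each vertex is then normalized. Without an incoming edge it keeps its
raw relation. With one (nearest preceding head wins), the rule table
applies:

| rule | pattern | output |
|------|---------|--------|
| R1 | parent → brother | (Uncle, side of parent) |
| R2 | parent → sister | (Aunt, side of parent) |
| R3 | parent → mother/father/parent | (Grandmother/Grandfather/Grandparent, side of parent) |
| R4 | sibling → son/daughter/child | suppressed (niece/nephew, excluded) |
| R5 | aunt/uncle → son/daughter/child | (Cousin, side of the aunt/uncle) |
| R6 | grandparent → cousin | suppressed (too distant) |

Chains covered by no rule (e.g. grandparent → brother: a great-uncle)
are suppressed as too distant. Each rule is individually toggleable
(`fm.rules.enabled`); a disabled rule reverts its pattern to the
default raw-relation behavior, and with *all* rules disabled the edges
are ignored entirely — the no-rules baseline.

Side of family: `Mother`-class heads fix Maternal, `Father`-class
Paternal; otherwise a heuristic takes the **last** occurrence of
*maternal*/*mother* vs *paternal*/*father* before the mention
(whole-document scan; NA when none precedes). First-degree relatives
always carry side NA, per the task convention. Document-level output
is the union of per-sentence sets.

## Paragraph validity filter

Notes regularly describe the partner's family, which must yield no
annotations although the sentences look identical to valid content.
The filter is a binary classifier over (previous paragraph, paragraph)
pairs: logistic regression on unigram+bigram counts of
`prev ⊕ marker ⊕ text`. Labels follow the task rule — a paragraph is
valid iff at least one gold annotation lies in its scope. When gold
carries no offsets, `derive_labels` locates evidence by string/rule
matching; this is best-effort and can mislabel a partner paragraph
whose rule output coincides with genuine gold (both families have a
"mother"), so corpora that carry explicit in-scope labels (the
synthetic generator does) should train on those. The decision
threshold is deliberately below 0.5 (default 0.3, configurable):
filtering is worth it only when clearly-invalid paragraphs are
removed, since a false invalid costs recall on every annotation the
paragraph held.

## Evaluation

FamilyMember triplets match exactly — a wrong side penalizes both
precision and recall, since the erroneous pair is a false positive
*and* the gold pair stays unmatched. Observation matching accepts
partial matches: contiguous token-sequence containment, case-folded,
in either direction (*diabetes* ↔ *diabetes type 2*), with greedy
one-to-one assignment (longest gold first) so one prediction cannot
satisfy several golds. Micro P/R/F1 pool per-document TP/FP/FN; empty
denominators score 0 with a warning (1.0 only when both sides are
empty).

System comparison uses the paired approximate randomization test:
each document's two outputs are swapped independently with probability
½ per shuffle (9999 by default) and
`p = (#{|ΔF1*| ≥ |ΔF1|} + 1)/(N + 1)`. Stratifying the swap by
document is the standard choice for paired system comparison; the
add-one smoothing keeps p in (0, 1].

## Synthetic corpus

The generator samples a kinship-consistent family (sided relatives
imply the corresponding parent; cousins imply an aunt/uncle on that
side; at least one first-degree relative), assigns diseases from a
bundled ~200-entry lexicon (with nested names like *diabetes* /
*diabetes type 2*, and mental-health/substance entries), and renders
one template sentence per relative. Core templates are exactly
invertible by the rule engine, so with all distractor probabilities at
zero the annotator should score FM F1 = 1.0 — this is the
template-coverage check, not a claim about real notes. Distractor
phenomena are gated by per-document probabilities (defaults chosen as
a realistic mix): partner-family paragraphs (0.3), enumerations
(0.3, including the rules-deficient "a son and a daughter" shape),
cross-sentence pronoun chains (0.2), negated general contexts (0.35),
non-mention usages like "on her father's side" (0.15), sibling's kids
(0.2) and too-distant relatives (0.1). Gold is emitted from the
sampled structure, never by re-parsing the rendered text, and
distractor content contributes no gold; negation/partner diseases are
drawn disjoint from the document's gold diseases so tag projection
stays exact. Same config + seed reproduces the corpus byte for byte.

What the generator does **not** emulate: clinical shorthand and typos,
section headers, de-identification artifacts, long coreference chains,
annotator disagreement, and the long-tailed phrasing of real notes.
Consequently the synthetic scores (FM F1 ≈ 0.93–1.0, observation F1 ≈
0.97) certify the machinery — rule inversion, filter direction,
trainability, transfer — not real-corpus performance, which for
systems of this family sits near F1 0.8.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale conditions chosen for a
single CPU: 60–100 notes per corpus, 10–12 training epochs, 9999
shuffles for significance tests (499 inside the 200-replicate null
calibration, where smaller shuffle counts make the p-value
distribution too discrete). Exhaustive-enumeration oracles check CRF
inference at n ≤ 5, T = 3; gradients are checked against central
finite differences at 10⁻⁶ step. Known numerical choices: log-space
recursions throughout; −10³⁰ as the masking constant; Viterbi
tie-break toward low tag indices; L2 regularization excluded from the
likelihood used in gradient checks (it is applied in the update).

## Limitations

Rule normalization only sees adjacent candidate pairs, so enumerations
("a son and a daughter who…") and multi-sentence reference chains
produce the same error classes observed in real systems. The encoder
is lexical; it cannot generalize to disease names unseen in training
beyond their context and subword shape. `derive_labels` is heuristic in
the absence of annotation offsets. The significance test assumes
per-document independence of the paired outputs.
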