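# fhx — family-history extraction from clinical notes

Family-history (FH) notes record the diseases of a patient's relatives
in free text; structuring them matters for genetic and familial-risk
assessment, and the information is locked in phrasings like *"Her
mother's sister has arthritis."* `fhx` is a hybrid entity-extraction
pipeline for such notes, for clinical-NLP researchers and anyone who
needs a reproducible, fully inspectable FH baseline:

- **Observation tagging** — disease mentions, formulated as BIO
  sequence tagging with a linear-chain conditional random field over a
  sparse lexical encoder. The CRF scores a tag sequence as
  `Σᵢ P[i,yᵢ] + Σᵢ A[yᵢ,yᵢ₊₁]` (+ boundary terms) with exact forward
  log-partition and Viterbi decoding, trained by gradient ascent on the
  conditional log-likelihood; an auxiliary disease-NER corpus can be
  used for intermediate-task pretraining before fine-tuning.
- **FamilyMember annotation** — a rule/graph system: relationship-word
  candidates, a directed "is-relative-of" graph from the patterns
  `X's *Y`, `X *has/had *Y`, `Y of *X` over sentence bigrams, and
  normalization rules (uncle, aunt, grandparents, sibling's-kids,
  cousin ×2) producing document-level `(relative, side)` pairs, with a
  last-cue *maternal/paternal* side heuristic.
- **Paragraph filtering** — a logistic-regression validity classifier
  that screens out partner-family paragraphs before annotation.
- **Evaluation** — document-level set-based micro P/R/F1 with partial
  observation matching (*diabetes* matches *diabetes type 2*) and a
  paired approximate randomization significance test.
- **Synthetic corpus generator** — multi-paragraph FH notes with exact
  gold annotations by construction, including partner-family
  distractors, enumerations, pronoun chains and negated contexts, so
  the whole pipeline is trainable and testable without restricted
  clinical data.

## Worked example

```python
from fhx.preprocess import segment
from fhx.family import annotate_document, AnnotatorConfig

doc = segment("note", "Her mother's sister has arthritis. "
                      "Her paternal grandmother had diabetes type 2.")
for a in sorted(annotate_document(doc, AnnotatorConfig()),
                key=lambda a: a.relative):
    print(f"{a.relative}\t{a.side}")
```

prints

```
Aunt	Maternal
Grandmother	Paternal
Mother	NA
```

`mother's sister` triggers the possessive pattern: an edge Mother→Sister
in the candidate graph, which the aunt rule rewrites to (Aunt, Maternal)
while the head keeps (Mother, NA). The standalone `grandmother` takes
its side from the nearest preceding side cue (*paternal*).

The same workflow from the shell, on a generated corpus:

```bash
fhx simulate --n 12 --seed 7 --out corpus
fhx train-filter --train corpus --gold corpus/gold.tsv --model filter.joblib --seed 0
fhx train-ner    --train corpus --gold corpus/gold.tsv --model ner.json --epochs 4 --dev-docs 3
fhx annotate --in corpus --out pred.tsv --ner-model ner.json --filter-model filter.joblib
fhx evaluate --gold corpus/gold.tsv --pred pred.tsv
```

```
FamilyMember tp=66 fp=4 fn=1 P=94.29 R=98.51 F1=96.35
Observation  tp=55 fp=2 fn=10 P=96.49 R=84.62 F1=90.16
combined     tp=121 fp=6 fn=11 P=95.28 R=91.67 F1=93.44
```

Counts are document-level set counts (a disease mentioned twice in one
note counts once); precision/recall/F1 are micro-averaged percentages.
The observation recall here reflects the deliberately tiny training run
(4 epochs, 12 notes); see `docs/methods.md` for the defaults.
`fhx sigtest --gold ... --pred-a ... --pred-b ...` compares two
prediction files with the randomization test.

## Layout

```
src/fhx/
  model.py       document/annotation data model
  preprocess.py  paragraph/sentence/token segmentation with offsets
  crf.py         linear-chain CRF: scoring, partition, marginals, Viterbi
  tagger.py      observation tagger: encoder, gold projection, training
  family.py      candidate graph + normalization rules + side heuristic
  parfilter.py   paragraph validity filter
  evaluation.py  set-based scoring and randomization test
  simulate.py    synthetic FH note generator with gold by construction
  io.py, cli.py  corpus/annotation TSV I/O and the `fhx` command
  data/diseases.txt  bundled disease lexicon
```
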