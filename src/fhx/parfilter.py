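"""Paragraph validity filter.

Family-history notes routinely contain paragraphs about the patient's
partner's family, which must yield no annotations.  The filter is a
binary classifier over (previous paragraph, paragraph) pairs predicting
whether a paragraph is *valid* — i.e. contains patient-blood-relative
information.  Training labels are derived from gold annotations: a
paragraph is valid iff at least one gold annotation is locatable within
its span.  At annotation time, sentences of paragraphs predicted
invalid are skipped.

The classifier is a logistic regression over unigram+bigram counts of
the previous paragraph, a separator marker, and the paragraph itself.
The decision cutoff is deliberately below 0.5 (default 0.3) so that
recall of valid paragraphs stays high and filtering mostly removes
clear-cut distractor content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .model import Document, FamilyMemberAnnotation, ObservationAnnotation

log = logging.getLogger(__name__)

_SEP = " xxparsep "


@dataclass(frozen=True)
class ParagraphExample:
    prev_text: str
    text: str
    label: bool  # True = valid


@dataclass
class FilterModel:
    """Trained paragraph classifier with a sub-0.5 decision threshold."""

    pipeline: Pipeline
    threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 0.5):
            raise ValueError("threshold must lie in (0, 0.5)")

    def predict_valid(self, prev_text: str, text: str) -> tuple[float, bool]:
        prob = float(self.pipeline.predict_proba(
            [prev_text + _SEP + text])[0, 1])
        return prob, prob >= self.threshold


def derive_labels(
    documents: list[Document],
    gold: dict[str, tuple[set[FamilyMemberAnnotation],
                          set[ObservationAnnotation]]],
) -> list[ParagraphExample]:
    """One training example per paragraph, labeled from gold evidence.

    A paragraph is valid iff gold evidence is locatable inside its span:
    either a gold observation string occurs in the paragraph text, or
    running the rule-based family-member annotator on the paragraph's
    sentences yields an annotation present in the document's gold set.
    """
    from .family import (AnnotatorConfig, RelationLexicon, build_graph,
                         detect_candidates, normalize_graph)

    examples: list[ParagraphExample] = []
    lexicon = RelationLexicon(15)
    cfg = AnnotatorConfig()
    for doc in documents:
        fm_gold, obs_gold = gold.get(doc.doc_id, (set(), set()))
        obs_lower = [o.text.lower() for o in obs_gold]
        prev_text = ""
        for para in doc.paragraphs:
            text = doc.text[para.start:para.end]
            tl = " ".join(text.lower().split())
            valid = any(o in tl for o in obs_lower)
            if not valid and fm_gold:
                prev_sent = None
                for sent in para.sentences:
                    cands = detect_candidates(sent, lexicon)
                    if cands:
                        graph = build_graph(
                            (prev_sent, sent), cands, [], (),
                            cfg.wildcard_max_tokens)
                        produced = normalize_graph(graph, doc,
                                                   cfg.rules_enabled)
                        if produced & fm_gold:
                            valid = True
                            break
                    prev_sent = sent
            examples.append(ParagraphExample(prev_text, text, valid))
            prev_text = text
    return examples


def examples_from_labels(
    documents: list[Document], labels: dict[str, list[bool]],
) -> list[ParagraphExample]:
    """Build training examples from explicit per-paragraph validity
    labels (e.g. carried by a corpus whose annotations are scoped to
    paragraphs, or by the synthetic generator's manifest)."""
    examples = []
    for doc in documents:
        doc_labels = labels[doc.doc_id]
        if len(doc_labels) != len(doc.paragraphs):
            raise ValueError(
                f"label/paragraph count mismatch for {doc.doc_id}")
        prev_text = ""
        for para, valid in zip(doc.paragraphs, doc_labels):
            text = doc.text[para.start:para.end]
            examples.append(ParagraphExample(prev_text, text, bool(valid)))
            prev_text = text
    return examples


def train_filter(
    examples: list[ParagraphExample],
    c: float = 1.0,
    seed: int = 0,
    threshold: float = 0.3,
) -> FilterModel:
    """Fit the logistic-regression paragraph classifier.

    Deterministic given ``seed``; raises on single-class data.
    """
    labels = [int(e.label) for e in examples]
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    texts = [e.prev_text + _SEP + e.text for e in examples]
    pipeline = Pipeline([
        ("bow", CountVectorizer(ngram_range=(1, 2), lowercase=True)),
        ("clf", LogisticRegression(C=c, max_iter=1000, random_state=seed)),
    ])
    pipeline.fit(texts, labels)
    return FilterModel(pipeline, threshold)
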