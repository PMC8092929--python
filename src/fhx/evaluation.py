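"""Document-level set-based scoring and significance testing.

A system emits, per document, a set of FamilyMember triplets
``(doc_id, relative, side)`` and Observation pairs ``(doc_id, text)``.
These sets are matched against gold: FamilyMember triplets match
exactly (the side is part of the triplet, so a wrong side penalizes
both precision and recall); Observation partial matches are accepted —
*diabetes* matches *diabetes type 2* — via contiguous token-sequence
containment in either direction, with greedy one-to-one assignment.
Duplicated mentions inside a document count once, by set semantics.

Micro precision/recall/F1 pool per-document TP/FP/FN counts.  System
pairs are compared with a paired approximate randomization test: each
document's two outputs are swapped with probability 1/2 per shuffle,
and the p-value is the smoothed fraction of shuffles whose absolute
statistic difference reaches the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import FamilyMemberAnnotation, ObservationAnnotation

log = logging.getLogger(__name__)

AnnotationSets = tuple[set[FamilyMemberAnnotation], set[ObservationAnnotation]]
PerDoc = dict[str, AnnotationSets]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    def as_percent(self) -> dict[str, float]:
        return {"precision": round(100 * self.precision, 2),
                "recall": round(100 * self.recall, 2),
                "f1": round(100 * self.f1, 2)}


@dataclass(frozen=True)
class SigTestResult:
    observed_diff: float
    p_value: float
    n_shuffles: int
    seed: int


def match_observation(pred_text: str, gold_text: str) -> bool:
    """Partial match: one token sequence contiguously contained in the
    other (case-folded, whitespace-normalized).  Symmetric."""
    a = tuple(pred_text.lower().split())
    b = tuple(gold_text.lower().split())
    if not a or not b:
        raise ValueError("observation strings must be non-empty")
    if len(a) > len(b):
        a, b = b, a
    return any(b[i:i + len(a)] == a for i in range(len(b) - len(a) + 1))


def score_document(
    pred: AnnotationSets, gold: AnnotationSets, entity_type: str,
) -> tuple[int, int, int]:
    """(tp, fp, fn) for one document and one entity type.

    FamilyMember: exact (relative, side) matching.  Observation: greedy
    one-to-one matching under the partial-match relation, longest gold
    first, so a single prediction cannot satisfy several golds.
    """
    if entity_type == "FamilyMember":
        p, g = pred[0], gold[0]
        tp = len(p & g)
        return tp, len(p) - tp, len(g) - tp
    if entity_type != "Observation":
        raise ValueError(f"unknown entity type {entity_type!r}")
    preds = sorted(o.text for o in pred[1])
    golds = sorted((o.text for o in gold[1]),
                   key=lambda t: (-len(t.split()), t))
    used = [False] * len(preds)
    tp = 0
    for g in golds:
        for i, p in enumerate(preds):
            if not used[i] and match_observation(p, g):
                used[i] = True
                tp += 1
                break
    return tp, len(preds) - tp, len(golds) - tp


def _prf(tp: int, fp: int, fn: int) -> EvalResult:
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
        if fn != 0:
            log.warning("no predictions against non-empty gold; precision=0")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvalResult(tp, fp, fn, precision, recall, f1)


def score_corpus(
    pred: PerDoc, gold: PerDoc, entity_type: str = "combined",
) -> EvalResult:
    """Micro-averaged P/R/F1 over the union of document ids.

    ``entity_type`` is "FamilyMember", "Observation" or "combined"
    (pooled counts of both types).
    """
    types = (["FamilyMember", "Observation"] if entity_type == "combined"
             else [entity_type])
    empty: AnnotationSets = (set(), set())
    tp = fp = fn = 0
    for doc_id in sorted(set(pred) | set(gold)):
        p = pred.get(doc_id, empty)
        g = gold.get(doc_id, empty)
        for t in types:
            dtp, dfp, dfn = score_document(p, g, t)
            tp += dtp
            fp += dfp
            fn += dfn
    return _prf(tp, fp, fn)


def approximate_randomization(
    gold: PerDoc,
    pred_a: PerDoc,
    pred_b: PerDoc,
    n_shuffles: int = 9999,
    seed: int = 0,
    entity_type: str = "combined",
) -> SigTestResult:
    """Paired approximate randomization test on the F1 difference.

    Per shuffle each document's (A, B) outputs are swapped independently
    with probability 1/2 and the F1 difference recomputed; the p-value
    is ``(#{|diff*| >= |observed|} + 1) / (n_shuffles + 1)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    doc_ids = sorted(set(gold) | set(pred_a) | set(pred_b))
    empty: AnnotationSets = (set(), set())
    types = (["FamilyMember", "Observation"] if entity_type == "combined"
             else [entity_type])

    # Precompute per-document counts for both assignments; a shuffle is
    # then just a choice of row per document.
    counts_a = np.zeros((len(doc_ids), 3), dtype=np.int64)
    counts_b = np.zeros((len(doc_ids), 3), dtype=np.int64)
    for k, doc_id in enumerate(doc_ids):
        g = gold.get(doc_id, empty)
        for t in types:
            counts_a[k] += score_document(pred_a.get(doc_id, empty), g, t)
            counts_b[k] += score_document(pred_b.get(doc_id, empty), g, t)

    def f1_of(c: np.ndarray) -> float:
        tp, fp, fn = c.sum(axis=0)
        res = _prf(int(tp), int(fp), int(fn))
        return res.f1

    observed = f1_of(counts_a) - f1_of(counts_b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        swap = rng.random(len(doc_ids)) < 0.5
        ca = np.where(swap[:, None], counts_b, counts_a)
        cb = np.where(swap[:, None], counts_a, counts_b)
        if abs(f1_of(ca) - f1_of(cb)) >= abs(observed):
            hits += 1
    p = (hits + 1) / (n_shuffles + 1)
    return SigTestResult(observed, p, n_shuffles, seed)
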