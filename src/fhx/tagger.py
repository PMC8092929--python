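"""Observation (disease mention) tagging with a feature-based CRF.

The tagger is a linear-chain CRF (:mod:`fhx.crf`) over per-token
emission scores from a sparse lexical encoder: lowercased word identity,
prefixes/suffixes, word shape, a +/-1 token window and an optional
in-disease-lexicon flag, each with one weight per tag.  The encoder is a
pluggable interface — anything that maps a token sequence to an
``n x T`` score matrix can sit under the same CRF layer.

Training maximizes the conditional log-likelihood of gold BIO sequences
by mini-batch gradient ascent; the per-epoch snapshot with the best
span-level F1 on a development split is returned.  An auxiliary NER
corpus can be used for intermediate-task pretraining: the model is first
trained on the auxiliary data, then fine-tuning continues from those
weights on the target corpus.

Gold BIO tags are not given by the corpus; they are recreated by string
matching the document-level gold annotation strings in the text.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import crf
from .crf import N_TAGS, TAG_INDEX, TAGS
from .model import Document, ObservationAnnotation, Sentence, normalize_ws

log = logging.getLogger(__name__)

_SERIAL_VERSION = 1


def _shape(word: str) -> str:
    out = []
    for ch in word:
        c = "X" if ch.isupper() else "x" if ch.islower() else \
            "d" if ch.isdigit() else ch
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


class LexiconEncoder:
    """Sparse linear token encoder: emission scores from lexical features.

    Weights live in a dict ``feature -> (T,) array``; unseen features
    score zero, so the encoder is usable before any training.
    """

    def __init__(self, lexicon: frozenset[str] | None = None) -> None:
        self.weights: dict[str, np.ndarray] = {}
        self.lexicon_tokens: frozenset[str] = frozenset(
            tok for entry in (lexicon or ())
            for tok in entry.lower().split()
        )

    def features(self, surfaces: list[str], i: int) -> list[str]:
        w = surfaces[i].lower()
        feats = [f"w={w}", f"shape={_shape(surfaces[i])}"]
        for k in (2, 3, 4):
            if len(w) > k:
                feats.append(f"pre{k}={w[:k]}")
                feats.append(f"suf{k}={w[-k:]}")
        feats.append(f"w-1={surfaces[i - 1].lower()}" if i > 0 else "w-1=<s>")
        feats.append(f"w-2={surfaces[i - 2].lower()}" if i > 1 else "w-2=<s>")
        feats.append(
            f"w+1={surfaces[i + 1].lower()}" if i + 1 < len(surfaces)
            else "w+1=</s>")
        feats.append(
            f"w+2={surfaces[i + 2].lower()}" if i + 2 < len(surfaces)
            else "w+2=</s>")
        if i > 1:
            feats.append(
                f"w-2,-1={surfaces[i - 2].lower()}_{surfaces[i - 1].lower()}")
        if w in self.lexicon_tokens:
            feats.append("inlex=1")
        return feats

    def encode(self, surfaces: list[str]) -> np.ndarray:
        P = np.zeros((len(surfaces), N_TAGS))
        for i in range(len(surfaces)):
            for f in self.features(surfaces, i):
                w = self.weights.get(f)
                if w is not None:
                    P[i] += w
        return P

    def accumulate(self, surfaces: list[str], d_scores: np.ndarray,
                   grads: dict[str, np.ndarray]) -> None:
        """Chain emission-score gradients into feature-weight gradients."""
        for i in range(len(surfaces)):
            for f in self.features(surfaces, i):
                g = grads.get(f)
                if g is None:
                    g = grads[f] = np.zeros(N_TAGS)
                g += d_scores[i]


@dataclass
class CrfModel:
    """CRF tag-transition parameters plus the token encoder."""

    encoder: LexiconEncoder = field(default_factory=LexiconEncoder)
    transitions: np.ndarray = field(
        default_factory=lambda: np.zeros((N_TAGS, N_TAGS)))
    start: np.ndarray = field(default_factory=lambda: np.zeros(N_TAGS))
    stop: np.ndarray = field(default_factory=lambda: np.zeros(N_TAGS))

    def emissions(self, surfaces: list[str]) -> np.ndarray:
        return self.encoder.encode(surfaces)

    def decode_tags(self, surfaces: list[str]) -> list[str]:
        if not surfaces:
            return []
        path = crf.viterbi_decode(
            self.emissions(surfaces), self.transitions,
            self.start, self.stop)
        return [TAGS[t] for t in path]

    # -- serialization ------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "version": _SERIAL_VERSION,
            "tags": list(TAGS),
            "transitions": self.transitions.tolist(),
            "start": self.start.tolist(),
            "stop": self.stop.tolist(),
            "lexicon_tokens": sorted(self.encoder.lexicon_tokens),
            "weights": {f: w.tolist()
                        for f, w in sorted(self.encoder.weights.items())},
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CrfModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("version") != _SERIAL_VERSION:
            raise ValueError("unsupported model file version")
        if tuple(payload["tags"]) != TAGS:
            raise ValueError("model tag alphabet mismatch")
        enc = LexiconEncoder()
        enc.lexicon_tokens = frozenset(payload["lexicon_tokens"])
        enc.weights = {f: np.array(w) for f, w in payload["weights"].items()}
        return cls(enc, np.array(payload["transitions"]),
                   np.array(payload["start"]), np.array(payload["stop"]))


# ---------------------------------------------------------------------
# Gold projection and BIO span codec
# ---------------------------------------------------------------------

def project_gold_tags(
    document: Document, gold: set[ObservationAnnotation],
) -> list[tuple[Sentence, list[str]]]:
    """Recreate per-sentence BIO tag sequences from gold strings.

    Every case-insensitive occurrence of each gold annotation string at
    token boundaries receives ``B-Observation I-Observation ...`` tags;
    longer gold strings win over shorter overlapping ones.  Gold strings
    that never occur in the document are logged as warnings (such gold
    errors do occur in shared-task data).
    """
    gold_tokens = sorted(
        ((tuple(g.text.lower().split()), g.text) for g in gold),
        key=lambda p: -len(p[0]))
    found: set[str] = set()
    out: list[tuple[Sentence, list[str]]] = []
    for sent in document.sentences():
        surfaces = [t.surface.lower() for t in sent.tokens]
        tags = ["O"] * len(surfaces)
        covered = [False] * len(surfaces)
        for gtoks, gtext in gold_tokens:
            m = len(gtoks)
            if m == 0:
                continue
            for i in range(len(surfaces) - m + 1):
                if any(covered[i:i + m]):
                    continue
                if tuple(surfaces[i:i + m]) == gtoks:
                    tags[i] = "B-Observation"
                    for j in range(i + 1, i + m):
                        tags[j] = "I-Observation"
                    covered[i:i + m] = [True] * m
                    found.add(gtext)
        out.append((sent, tags))
    for _, gtext in gold_tokens:
        if gtext not in found:
            log.warning(
                "gold observation %r not found in document %s",
                gtext, document.doc_id)
    return out


def spans_from_tags(tags: list[str]) -> list[tuple[int, int]]:
    """Token index spans ``[i, j)`` of maximal ``B (I)*`` runs."""
    spans = []
    i = 0
    while i < len(tags):
        if tags[i] == "B-Observation":
            j = i + 1
            while j < len(tags) and tags[j] == "I-Observation":
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def decode_observations(
    document: Document, model: CrfModel,
) -> set[ObservationAnnotation]:
    """Document-level set of Observation mentions from per-sentence Viterbi."""
    result: set[ObservationAnnotation] = set()
    for sent in document.sentences():
        surfaces = [t.surface for t in sent.tokens]
        tags = model.decode_tags(surfaces)
        for i, j in spans_from_tags(tags):
            text = document.text[sent.tokens[i].start:sent.tokens[j - 1].end]
            result.add(ObservationAnnotation(text))
    return result


def dictionary_tagger(
    document: Document, lexicon: set[str] | frozenset[str],
) -> set[ObservationAnnotation]:
    """Longest-match, case-insensitive lexicon tagging at token boundaries."""
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    entries = sorted(
        {tuple(e.lower().split()) for e in lexicon if e.strip()},
        key=len, reverse=True)
    result: set[ObservationAnnotation] = set()
    for sent in document.sentences():
        surfaces = [t.surface.lower() for t in sent.tokens]
        covered = [False] * len(surfaces)
        for ent in entries:
            m = len(ent)
            for i in range(len(surfaces) - m + 1):
                if any(covered[i:i + m]):
                    continue
                if tuple(surfaces[i:i + m]) == ent:
                    covered[i:i + m] = [True] * m
                    text = document.text[
                        sent.tokens[i].start:sent.tokens[i + m - 1].end]
                    result.add(ObservationAnnotation(text))
    return result


# ---------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------

TaggedSentence = tuple[list[str], list[str]]  # (surfaces, BIO tags)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.2
    epochs: int = 15
    batch_size: int = 8
    l2: float = 1e-4
    seed: int = 0


def loglik_and_grad(
    model: CrfModel, batch: list[TaggedSentence],
) -> tuple[float, dict]:
    """Conditional log-likelihood of the batch and its full gradient.

    Gradient of log p(y|x) w.r.t. an emission score is the gold
    indicator minus the posterior node marginal; w.r.t. a transition it
    is the gold pair count minus the posterior edge marginal.
    """
    ll = 0.0
    g_trans = np.zeros((N_TAGS, N_TAGS))
    g_start = np.zeros(N_TAGS)
    g_stop = np.zeros(N_TAGS)
    g_feats: dict[str, np.ndarray] = {}
    for surfaces, tags in batch:
        if not surfaces:
            continue
        y = np.array([TAG_INDEX[t] for t in tags])
        P = model.emissions(surfaces)
        node, edge, logZ = crf.forward_backward(
            P, model.transitions, model.start, model.stop)
        ll += crf.sequence_score(
            P, y, model.transitions, model.start, model.stop) - logZ
        d_scores = -node
        d_scores[np.arange(len(y)), y] += 1.0
        model.encoder.accumulate(surfaces, d_scores, g_feats)
        g_start[y[0]] += 1.0
        g_start -= node[0]
        g_stop[y[-1]] += 1.0
        g_stop -= node[-1]
        for i in range(len(y) - 1):
            g_trans[y[i], y[i + 1]] += 1.0
        if len(y) > 1:
            g_trans -= edge.sum(axis=0)
    return ll, {"transitions": g_trans, "start": g_start,
                "stop": g_stop, "features": g_feats}


def span_f1(model: CrfModel, data: list[TaggedSentence]) -> float:
    """Span-level F1 of Viterbi output against gold BIO spans."""
    tp = fp = fn = 0
    for surfaces, tags in data:
        if not surfaces:
            continue
        pred = set(spans_from_tags(model.decode_tags(surfaces)))
        gold = set(spans_from_tags(tags))
        tp += len(pred & gold)
        fp += len(pred - gold)
        fn += len(gold - pred)
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_crf(
    train: list[TaggedSentence],
    dev: list[TaggedSentence] | None = None,
    config: TrainConfig | None = None,
    model: CrfModel | None = None,
    lexicon: frozenset[str] | None = None,
) -> CrfModel:
    """Mini-batch gradient ascent on the conditional log-likelihood.

    Returns the epoch snapshot with the best dev span-level F1 (the
    final model when no dev split is given).  Deterministic given the
    seed in ``config``.
    """
    if not train:
        raise ValueError("training corpus is empty")
    config = config or TrainConfig()
    if model is None:
        model = CrfModel(encoder=LexiconEncoder(lexicon))
    rng = np.random.default_rng(config.seed)
    best_f1 = -1.0
    best_model: CrfModel | None = None
    history: list[float] = []
    n = len(train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_ll = 0.0
        for bstart in range(0, n, config.batch_size):
            batch = [train[i] for i in order[bstart:bstart + config.batch_size]]
            ll, grads = loglik_and_grad(model, batch)
            total_ll += ll
            lr = config.learning_rate / max(len(batch), 1)
            model.transitions += lr * (
                grads["transitions"] - config.l2 * model.transitions)
            model.start += lr * (grads["start"] - config.l2 * model.start)
            model.stop += lr * (grads["stop"] - config.l2 * model.stop)
            for f, g in grads["features"].items():
                w = model.encoder.weights.get(f)
                if w is None:
                    w = model.encoder.weights[f] = np.zeros(N_TAGS)
                w += lr * (g - config.l2 * w)
        history.append(training_loglik(model, train))
        if dev:
            f1 = span_f1(model, dev)
            log.info("epoch %d: train ll=%.3f dev span F1=%.4f",
                     epoch, history[-1], f1)
            if f1 > best_f1:
                best_f1 = f1
                best_model = copy.deepcopy(model)
        else:
            log.info("epoch %d: train ll=%.3f", epoch, history[-1])
    out = best_model if best_model is not None else model
    out.train_loglik_history = history
    return out


def pretrain_then_finetune(
    aux: list[TaggedSentence],
    target: list[TaggedSentence],
    target_dev: list[TaggedSentence] | None = None,
    aux_config: TrainConfig | None = None,
    target_config: TrainConfig | None = None,
    lexicon: frozenset[str] | None = None,
) -> CrfModel:
    """Intermediate-task pretraining on an auxiliary NER corpus.

    The model is trained on ``aux`` with the same tag alphabet, then the
    same parameters continue training on ``target``.  An empty auxiliary
    corpus degenerates to plain target training.
    """
    model: CrfModel | None = None
    if aux:
        model = train_crf(aux, dev=None, config=aux_config, lexicon=lexicon)
    return train_crf(target, dev=target_dev, config=target_config,
                     model=model, lexicon=lexicon)


def training_loglik(model: CrfModel, data: list[TaggedSentence]) -> float:
    """Total conditional log-likelihood of ``data`` (no gradient)."""
    ll = 0.0
    for surfaces, tags in data:
        if not surfaces:
            continue
        y = np.array([TAG_INDEX[t] for t in tags])
        P = model.emissions(surfaces)
        ll += crf.sequence_score(
            P, y, model.transitions, model.start, model.stop)
        ll -= crf.log_partition(P, model.transitions, model.start, model.stop)
    return ll
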