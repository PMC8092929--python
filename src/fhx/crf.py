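"""Linear-chain conditional random field over BIO tag sequences.

A sentence of ``n`` tokens is scored against a tag sequence
``y = (y_1 .. y_n)`` as

    score(X, y) = start[y_1] + sum_i P[i, y_i]
                + sum_i A[y_i, y_{i+1}] + stop[y_n]

where ``P`` holds per-token emission scores produced by an encoder and
``A`` is the tag-transition compatibility matrix.  The conditional
probability of a sequence is ``exp(score) / Z`` with the partition
function ``Z`` summing ``exp(score)`` over all ``T^n`` sequences; it is
computed exactly by the forward recursion in log space.  Decoding finds
the maximum-probability sequence with Viterbi; ties resolve to the
lexicographically smallest tag-index sequence.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

#: Tag alphabet for Observation tagging, in index order.  ``O`` first so
#: that tie-breaking toward low indices prefers the empty annotation.
TAGS: tuple[str, ...] = ("O", "B-Observation", "I-Observation")
TAG_INDEX: dict[str, int] = {t: i for i, t in enumerate(TAGS)}
N_TAGS = len(TAGS)

NEG_INF = -1e30  # finite stand-in for -inf; keeps arithmetic NaN-free


def bio_transition_mask(tags: tuple[str, ...] = TAGS) -> tuple[np.ndarray, np.ndarray]:
    """(start_mask, transition_mask) with ``NEG_INF`` on BIO-invalid moves.

    An ``I-`` tag may not open a sequence and may not follow ``O`` (or an
    ``I-``/``B-`` of a different type, were there several).
    """
    T = len(tags)
    start = np.zeros(T)
    trans = np.zeros((T, T))
    for j, tj in enumerate(tags):
        if tj.startswith("I-"):
            start[j] = NEG_INF
            for i, ti in enumerate(tags):
                ok = (ti == "B-" + tj[2:]) or (ti == tj)
                if not ok:
                    trans[i, j] = NEG_INF
    return start, trans


def sequence_score(
    emissions: np.ndarray,
    tag_ids: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
) -> float:
    """Unnormalized log-score of one tag sequence."""
    emissions = np.asarray(emissions, dtype=float)
    tag_ids = np.asarray(tag_ids, dtype=int)
    n = emissions.shape[0]
    if tag_ids.shape[0] != n:
        raise ValueError(
            f"length mismatch: {n} tokens vs {tag_ids.shape[0]} tags")
    s = start[tag_ids[0]] + stop[tag_ids[-1]]
    s += emissions[np.arange(n), tag_ids].sum()
    s += transitions[tag_ids[:-1], tag_ids[1:]].sum()
    return float(s)


def log_partition(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
) -> float:
    """log Z: log-sum-exp of the score over all tag sequences."""
    emissions = np.asarray(emissions, dtype=float)
    n, T = emissions.shape
    if n < 1:
        raise ValueError("need at least one token")
    alpha = start + emissions[0]
    for i in range(1, n):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[i]
    return float(logsumexp(alpha + stop))


def forward_backward(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior node and edge marginals under the CRF.

    Returns ``(node, edge, logZ)`` with ``node[i, t] = p(y_i = t)`` and
    ``edge[i, a, b] = p(y_i = a, y_{i+1} = b)``.
    """
    emissions = np.asarray(emissions, dtype=float)
    n, T = emissions.shape
    alpha = np.empty((n, T))
    alpha[0] = start + emissions[0]
    for i in range(1, n):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + transitions, axis=0) \
            + emissions[i]
    beta = np.empty((n, T))
    beta[-1] = stop
    for i in range(n - 2, -1, -1):
        beta[i] = logsumexp(
            transitions + emissions[i + 1] + beta[i + 1], axis=1)
    logZ = float(logsumexp(alpha[-1] + stop))
    node = np.exp(alpha + beta - logZ)
    edge = np.empty((max(n - 1, 0), T, T))
    for i in range(n - 1):
        logm = (alpha[i][:, None] + transitions
                + emissions[i + 1] + beta[i + 1] - logZ)
        edge[i] = np.exp(logm)
    return node, edge, logZ


def viterbi_decode(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    enforce_bio: bool = True,
) -> np.ndarray:
    """Argmax tag-id sequence; ties -> lexicographically smallest ids.

    With ``enforce_bio`` the BIO-invalid moves (start -> I, O -> I) are
    masked to effectively minus infinity, so output is always valid BIO.

    Implementation: a backward pass computes the best achievable suffix
    score per (position, tag); a forward greedy pass then picks, left to
    right, the lowest tag index attaining the global maximum, which
    yields the lexicographic minimum among all optimal sequences.
    """
    emissions = np.asarray(emissions, dtype=float)
    n, T = emissions.shape
    if n < 1:
        raise ValueError("need at least one token")
    if enforce_bio:
        smask, tmask = bio_transition_mask(TAGS[:T] if T == N_TAGS else
                                           tuple(f"t{i}" for i in range(T)))
        start = start + smask
        transitions = transitions + tmask

    # best[i, t]: best score of the suffix y_i..y_n given y_i = t,
    # including emissions from i on, transitions from i on, and stop.
    best = np.empty((n, T))
    best[-1] = emissions[-1] + stop
    for i in range(n - 2, -1, -1):
        best[i] = emissions[i] + np.max(transitions + best[i + 1], axis=1)

    path = np.empty(n, dtype=int)
    totals = start + best[0]
    path[0] = int(np.flatnonzero(totals == totals.max())[0])
    for i in range(1, n):
        cand = transitions[path[i - 1]] + best[i]
        path[i] = int(np.flatnonzero(cand == cand.max())[0])
    return path
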