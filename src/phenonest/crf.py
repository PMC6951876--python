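"""Linear-chain CRF potentials: scoring, forward algorithm, Viterbi, NLL.

A path ``y_1..y_T`` over ``K`` tags is scored as

    s(y) = start[y_1] + sum_t emissions[t, y_t]
         + sum_t transitions[y_{t-1}, y_t] + end[y_T]

with virtual start/stop potentials.  ``log_partition`` is the log-sum-exp
of ``s`` over all ``K^T`` paths (forward algorithm, computed in log space);
``viterbi`` returns an argmax path with deterministic lowest-tag-index
tie-breaking; ``nll`` is ``log_partition - s(gold)``.

These are the inference-time primitives; training differentiates an
equivalent computation built on :mod:`phenonest._autodiff`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

#: additive penalty used to (effectively) forbid a transition while keeping
#: all scores finite
MASK_PENALTY = -1e4


def _check(emissions: np.ndarray, transitions: np.ndarray) -> None:
    if emissions.ndim != 2:
        raise ValueError(f"emissions must be (T, K), got shape {emissions.shape}")
    K = emissions.shape[1]
    if transitions.shape != (K, K):
        raise ValueError(f"transitions must be ({K}, {K}), got {transitions.shape}")


def _boundary(K: int, v: np.ndarray | None) -> np.ndarray:
    return np.zeros(K) if v is None else np.asarray(v, dtype=float)


def sequence_score(
    emissions: np.ndarray,
    transitions: np.ndarray,
    tags: np.ndarray,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """Unnormalized log-potential of one tag path."""
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    _check(emissions, transitions)
    tags = np.asarray(tags, dtype=int)
    if tags.shape[0] != emissions.shape[0]:
        raise ValueError(f"{tags.shape[0]} tags for {emissions.shape[0]} positions")
    K = emissions.shape[1]
    start = _boundary(K, start)
    end = _boundary(K, end)
    score = start[tags[0]] + emissions[np.arange(len(tags)), tags].sum() + end[tags[-1]]
    score += transitions[tags[:-1], tags[1:]].sum()
    return float(score)


def log_partition(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """Forward-algorithm log normalizer over all tag paths."""
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    _check(emissions, transitions)
    K = emissions.shape[1]
    alpha = _boundary(K, start) + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha + _boundary(K, end)))


def viterbi(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Max-scoring tag path and its score.

    Ties are broken toward the lowest tag index at the latest step where
    competing optimal paths diverge (``argmax`` keeps the first maximum at
    every backpointer and at the final state).
    """
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    _check(emissions, transitions)
    T, K = emissions.shape
    delta = _boundary(K, start) + emissions[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + transitions  # (prev, cur)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + emissions[t]
    delta = delta + _boundary(K, end)
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, sequence_score(emissions, transitions, path, start, end)


def nll(
    emissions: np.ndarray,
    transitions: np.ndarray,
    tags: np.ndarray,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    return log_partition(emissions, transitions, start, end) - sequence_score(
        emissions, transitions, tags, start, end
    )


def bio_transition_mask(tag_names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive masks forbidding malformed BIO transitions.

    Returns ``(transition_mask, start_mask, end_mask)`` with 0 for allowed
    moves and :data:`MASK_PENALTY` for ``O -> I-x``, ``B-x -> I-y``,
    ``I-x -> I-y`` (x != y) and path starts at ``I-x``.
    """
    K = len(tag_names)
    trans = np.zeros((K, K))
    start = np.zeros(K)
    end = np.zeros(K)
    def cat(name: str) -> tuple[str, str]:
        prefix, _, c = name.partition("-")
        return prefix, c
    for j, nj in enumerate(tag_names):
        pj, cj = cat(nj)
        if pj == "I":
            start[j] = MASK_PENALTY
        for i, ni in enumerate(tag_names):
            pi, ci = cat(ni)
            if pj == "I" and not (pi in ("B", "I") and ci == cj):
                trans[i, j] = MASK_PENALTY
    return trans, start, end
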