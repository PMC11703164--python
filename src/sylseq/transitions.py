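"""Syllable-level Markov structure: transition matrices, steady state,
entropy rate, and transition frequency.

Transitions are counted between consecutive *distinct* syllables (the
run-length-encoded sequence), so the matrix has a zero diagonal and
describes which module follows which, independent of dwell times.  The
entropy rate H = -sum_ij pi_i A_ij ln A_ij summarizes how predictable
the sequencing is; the unweighted sum of row entropies is reported
alongside it as an alternative aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .metrics import InvalidInputError, run_length_encode

__all__ = [
    "TransitionModel",
    "TransitionDiff",
    "estimate_transition_matrix",
    "steady_state",
    "entropy_rate",
    "transition_frequency",
    "transition_model",
    "group_transition_summary",
]


@dataclass
class TransitionModel:
    syllables: np.ndarray          # (S,) syllable ids, ascending
    A: np.ndarray                  # (S,S) zero-diagonal transition matrix
    pi: np.ndarray | None = None   # steady state (0 outside the recurrent class)
    entropy: float | None = None            # pi-weighted entropy rate (nats by default)
    row_entropy_sum: float | None = None    # unweighted sum of row entropies
    transition_frequency: float | None = None  # syllable change-points per second
    zero_rows: np.ndarray | None = None     # syllables never exited in-sample


@dataclass
class TransitionDiff:
    """Entrywise group-mean difference (group2 - group1) with sign labels."""

    syllables: np.ndarray
    delta: np.ndarray
    group1: str
    group2: str
    threshold: float = 0.0

    @property
    def edges(self):
        """(from, to, delta, sign) for entries above the display threshold."""
        out = []
        S = len(self.syllables)
        for i in range(S):
            for j in range(S):
                d = self.delta[i, j]
                if i != j and abs(d) > self.threshold:
                    out.append((int(self.syllables[i]), int(self.syllables[j]),
                                float(d), "up" if d > 0 else "down"))
        return out


def estimate_transition_matrix(
    labels: np.ndarray, syllable_ids: np.ndarray | None = None
) -> TransitionModel:
    """Bigram estimate of the inter-syllable transition matrix.

    Counts consecutive pairs of the run-length-encoded sequence and
    row-normalizes.  Syllables with no outgoing transitions keep a zero
    row and are flagged (absorbing in-sample).
    """
    rle = run_length_encode(np.asarray(labels))
    seq = np.array([s for s, _, _ in rle])
    if seq.size < 2:
        raise InvalidInputError("need at least 2 syllable instances")
    if syllable_ids is None:
        syllable_ids = np.unique(seq)
    syllable_ids = np.asarray(syllable_ids)
    index = {int(s): k for k, s in enumerate(syllable_ids)}
    S = len(syllable_ids)
    C = np.zeros((S, S))
    for a, b in zip(seq[:-1], seq[1:]):
        C[index[int(a)], index[int(b)]] += 1
    tot = C.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    A = np.divide(C, tot, out=np.zeros_like(C), where=tot > 0)
    return TransitionModel(syllables=syllable_ids, A=A, zero_rows=zero)


def _largest_recurrent_class(A: np.ndarray) -> np.ndarray:
    """Indices of the largest recurrent (closed) communicating class."""
    S = A.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(S))
    for i, j in zip(*np.nonzero(A > 0)):
        G.add_edge(int(i), int(j))
    best: list[int] = []
    for scc in nx.strongly_connected_components(G):
        closed = all(j in scc for i in scc for j in G.successors(i))
        # zero-out-degree singletons (never exited in-sample) are not recurrent
        has_edges = any(True for i in scc for _ in G.successors(i))
        if closed and has_edges and len(scc) > len(best):
            best = sorted(scc)
    return np.array(best, dtype=int)


def steady_state(A: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000) -> np.ndarray:
    """Stationary distribution pi with pi A = pi.

    Restricted to the largest recurrent communicating class (states
    outside it get pi = 0); computed by damped power iteration
    p <- p (I + A)/2, which converges even for periodic chains, until
    the residual ||pi A - pi||_inf falls below ``tol``.
    """
    A = np.asarray(A, float)
    if A.size == 0:
        raise InvalidInputError("empty transition matrix")
    rec = _largest_recurrent_class(A)
    if rec.size == 0:
        raise InvalidInputError("no recurrent class")
    B = A[np.ix_(rec, rec)]
    p = np.full(len(rec), 1.0 / len(rec))
    for _ in range(max_iter):
        nxt = 0.5 * (p + p @ B)
        nxt /= nxt.sum()
        if np.abs(nxt @ B - nxt).max() < tol:
            p = nxt
            break
        p = nxt
    pi = np.zeros(A.shape[0])
    pi[rec] = p
    return pi


def entropy_rate(A: np.ndarray, pi: np.ndarray, base: float | None = None) -> tuple[float, float]:
    """(entropy rate, unweighted row-entropy sum), natural log by default.

    H = -sum_ij pi_i A_ij log A_ij with 0 log 0 := 0.  ``base=2`` gives
    bits.  Zero-pi states contribute nothing to H but their rows still
    enter the unweighted sum when they have outgoing mass.
    """
    A = np.asarray(A, float)
    pi = np.asarray(pi, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logA = np.where(A > 0, np.log(A), 0.0)
    if base is not None:
        logA = logA / np.log(base)
    row_h = -(A * logA).sum(axis=1)
    H = float((pi * row_h).sum())
    return H, float(row_h.sum())


def transition_frequency(labels: np.ndarray, fps: float) -> float:
    """Syllable change-points per second of session."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise InvalidInputError("need at least 2 frames")
    n_changes = int((labels[1:] != labels[:-1]).sum())
    return n_changes / (labels.size / fps)


def transition_model(
    labels: np.ndarray,
    fps: float,
    syllable_ids: np.ndarray | None = None,
    base: float | None = None,
) -> TransitionModel:
    """Full per-animal transition summary: A, pi, entropies, frequency."""
    m = estimate_transition_matrix(labels, syllable_ids)
    m.pi = steady_state(m.A)
    m.entropy, m.row_entropy_sum = entropy_rate(m.A, m.pi, base=base)
    m.transition_frequency = transition_frequency(labels, fps)
    return m


def group_transition_summary(
    models: dict[str, TransitionModel],
    group_of: dict[str, str],
    pair: tuple[str, str] | None = None,
    threshold: float = 0.0,
) -> tuple[dict[str, TransitionModel], TransitionDiff | None]:
    """Entrywise group-mean transition matrices and their difference.

    Per-animal matrices are aligned on the union of syllable sets
    (missing syllables padded with zero rows/columns) and averaged
    within group.  When ``pair`` names two groups, the difference
    mean(A, group2) - mean(A, group1) is returned; swapping the pair
    negates it.
    """
    if not models:
        raise InvalidInputError("no models")
    union = np.unique(np.concatenate([m.syllables for m in models.values()]))
    idx = {int(s): k for k, s in enumerate(union)}
    S = len(union)

    by_group: dict[str, list[np.ndarray]] = {}
    for animal, m in models.items():
        big = np.zeros((S, S))
        loc = [idx[int(s)] for s in m.syllables]
        big[np.ix_(loc, loc)] = m.A
        by_group.setdefault(group_of[animal], []).append(big)

    means = {
        g: TransitionModel(syllables=union, A=np.mean(mats, axis=0))
        for g, mats in by_group.items()
    }
    diff = None
    if pair is not None:
        g1, g2 = pair
        diff = TransitionDiff(
            syllables=union,
            delta=means[g2].A - means[g1].A,
            group1=g1, group2=g2, threshold=threshold,
        )
    return means, diff
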