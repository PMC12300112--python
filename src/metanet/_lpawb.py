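"""Weighted bipartite modularity maximisation: label propagation plus
multi-step agglomeration (LPAwb+-style), optimising Barber's Q.

Q = (1/F) * sum_ij (w_ij - r_i c_j / F) * delta(g_i, g_j)

with F the total matrix weight and r, c the marginal totals.  Stage one
propagates labels between the two node sets, each node adopting the label
with the largest modularity gain; stage two greedily merges module pairs
whenever a merge increases Q, re-running propagation after each merge.
The search is stochastic (node order, tie-breaks), so several seeded
restarts are taken and the best partition kept.
"""

from __future__ import annotations

import numpy as np

__all__ = ["barber_modularity", "lpa_wb_plus"]


def barber_modularity(
    w: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray
) -> float:
    """Barber's weighted bipartite modularity for a given partition."""
    w = np.asarray(w, dtype=float)
    F = w.sum()
    if F <= 0:
        raise ValueError("total matrix weight must be positive")
    Bbar = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F
    same = row_labels[:, None] == col_labels[None, :]
    return float((Bbar * same).sum() / F)


def _propagate(
    Bbar: np.ndarray,
    row_labels: np.ndarray,
    col_labels: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Sweep label updates until a fixed point (in place)."""
    nr, nc = Bbar.shape
    fresh = int(max(row_labels.max(), col_labels.max())) + 1
    changed = True
    guard = 0
    while changed and guard < 200:
        changed = False
        guard += 1
        for own, other, b in [
            (col_labels, row_labels, Bbar.T),
            (row_labels, col_labels, Bbar),
        ]:
            for i in rng.permutation(len(own)):
                labels, scores = _label_scores(b[i], other)
                best_score = scores.max()
                if best_score >= 0:
                    best = labels[int(np.argmax(scores))]
                else:
                    # every module repels this node: defect to a singleton
                    best, best_score = fresh, 0.0
                    fresh += 1
                if best != own[i] and best_score > _score_of(b[i], other, own[i]):
                    own[i] = best
                    changed = True


def _label_scores(b: np.ndarray, other_labels: np.ndarray):
    labels = np.unique(other_labels)
    scores = np.array([b[other_labels == L].sum() for L in labels])
    return labels, scores


def _score_of(b: np.ndarray, other_labels: np.ndarray, label) -> float:
    return float(b[other_labels == label].sum())


def _agglomerate(
    Bbar: np.ndarray,
    F: float,
    row_labels: np.ndarray,
    col_labels: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Greedy module merging with propagation after each accepted merge."""
    while True:
        labels = np.unique(np.concatenate([row_labels, col_labels]))
        if labels.size < 2:
            return
        best_gain, best_pair = 0.0, None
        for ai in range(labels.size):
            for bi in range(ai + 1, labels.size):
                La, Lb = labels[ai], labels[bi]
                ra, ca = row_labels == La, col_labels == La
                rb, cb = row_labels == Lb, col_labels == Lb
                gain = (Bbar[np.ix_(ra, cb)].sum() + Bbar[np.ix_(rb, ca)].sum()) / F
                if gain > best_gain + 1e-15:
                    best_gain, best_pair = gain, (La, Lb)
        if best_pair is None:
            return
        La, Lb = best_pair
        row_labels[row_labels == Lb] = La
        col_labels[col_labels == Lb] = La
        _propagate(Bbar, row_labels, col_labels, rng)


def lpa_wb_plus(
    w: np.ndarray, rng: np.random.Generator, n_restarts: int = 20
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best (Q, row_labels, col_labels) over seeded restarts.

    The single-module partition (Q = 0) is always part of the search, so
    the reported Q is never negative.
    """
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty matrix")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    F = w.sum()
    if F <= 0:
        raise ValueError("total matrix weight must be positive")
    nr, nc = w.shape
    Bbar = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F

    best_q = 0.0
    best = (np.zeros(nr, dtype=int), np.zeros(nc, dtype=int))
    for restart in range(n_restarts):
        # vary the initial module count across restarts (coarse-to-fine
        # initialisations escape the local optima plain propagation hits)
        k = 1 + restart % nr
        row_labels = (
            rng.permutation(nr).astype(int) if k == nr else rng.integers(0, k, nr)
        )
        col_labels = np.full(nc, -1, dtype=int)
        for j in range(nc):
            labels, scores = _label_scores(Bbar[:, j], row_labels)
            col_labels[j] = labels[int(np.argmax(scores))]
        _propagate(Bbar, row_labels, col_labels, rng)
        _agglomerate(Bbar, F, row_labels, col_labels, rng)
        q = barber_modularity(w, row_labels, col_labels)
        if q > best_q:
            best_q = q
            best = (row_labels.copy(), col_labels.copy())
    return best_q, best[0], best[1]
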