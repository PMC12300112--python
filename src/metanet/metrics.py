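"""Structural and diversity metrics evaluated at equilibrium.

Covers total abundance, the Gini coefficient of the species-abundance
distribution, Morisita-Horn compositional similarity (spatial: among
local networks; temporal: meta-network with versus without dispersal),
abundance-weighted bipartite interaction matrices, weighted NODF
nestedness and Barber bipartite modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ._lpawb import lpa_wb_plus
from .dynamics import MetaState

__all__ = [
    "WeightedBipartiteMatrix",
    "MetricsRecord",
    "total_abundance",
    "gini",
    "gini_local_mean",
    "morisita_horn_spatial",
    "morisita_horn_temporal",
    "meta_relative_abundance",
    "weighted_matrix",
    "wnodf",
    "bipartite_modularity",
]


@dataclass(frozen=True)
class WeightedBipartiteMatrix:
    """Abundance-weighted plant x animal interaction matrix.

    ``scope`` is a local-network index or ``"meta"`` (weights summed over
    networks).  Weights are non-negative and vanish off the binary
    topology.
    """

    w: np.ndarray
    scope: int | str = "meta"

    def __post_init__(self) -> None:
        if self.w.ndim != 2:
            raise ValueError("weight matrix must be 2-d (plants x animals)")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class MetricsRecord:
    """One tidy row of metrics for a (scenario, mu_d, seed) cell."""

    scenario: str
    mu_d: float
    seed: int
    total_abundance: float | None = None
    gini_meta: float | None = None
    gini_local_mean: float | None = None
    mh_spatial: float | None = None
    mh_temporal: float | None = None
    wnodf_meta: float | None = None
    wnodf_local_mean: float | None = None
    modularity_meta: float | None = None
    modularity_local_mean: float | None = None
    leading_meta: float | None = None
    leading_local_mean: float | None = None
    group_distance: float | None = None
    residual: float | None = None
    converged: bool | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def total_abundance(xstar: MetaState) -> float:
    """Sum of equilibrium abundances of every species over every network."""
    return float(xstar.P.sum() + xstar.A.sum())


def gini(abundances: np.ndarray) -> float:
    """Gini coefficient of an abundance vector (0 = perfectly even).

    With abundances ranked increasingly,
    G = (1/S) * (S + 1 - 2 * sum_i (S + 1 - i) X_i / sum_i X_i).
    """
    x = np.sort(np.asarray(abundances, dtype=float).ravel())
    if x.size == 0 or (x < 0).any():
        raise ValueError("abundances must be a non-empty non-negative vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("Gini undefined for an all-zero abundance vector")
    S = x.size
    ranks = np.arange(1, S + 1)
    return float((S + 1 - 2.0 * np.sum((S + 1 - ranks) * x) / total) / S)


def gini_local_mean(xstar: MetaState) -> float:
    """Unweighted mean of the per-network Gini coefficients."""
    X = xstar.stacked()
    return float(np.mean([gini(X[:, k]) for k in range(xstar.n)]))


def morisita_horn_spatial(xstar: MetaState) -> float:
    """Multiple-assemblage Morisita-Horn similarity among local networks.

    C = 2 * sum_i sum_{j<k} p_ij p_ik / ((n-1) * sum_i sum_j p_ij^2) with
    p_ij the relative abundance of species i in network j; 1 for
    compositionally identical networks, 0 for disjoint ones.
    """
    X = xstar.stacked()
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every local network needs positive total abundance")
    p = X / totals
    n = p.shape[1]
    if n < 2:
        raise ValueError("need at least 2 local networks")
    rowsum = p.sum(axis=1)
    cross = 0.5 * (rowsum**2 - (p**2).sum(axis=1)).sum()  # sum_i sum_{j<k} p_ij p_ik
    return float(2.0 * cross / ((n - 1) * (p**2).sum()))


def meta_relative_abundance(xstar: MetaState) -> np.ndarray:
    """Species' relative abundances in the pooled meta-network (sums to 1)."""
    totals = xstar.stacked().sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("meta-network has zero total abundance")
    return totals / grand


def morisita_horn_temporal(q_before: np.ndarray, q_after: np.ndarray) -> float:
    """Two-assemblage Morisita-Horn similarity of relative abundances.

    C = 2 * sum q_b q_a / (sum q_b^2 + sum q_a^2); both inputs must be
    normalised to sum 1.
    """
    qb = np.asarray(q_before, dtype=float)
    qa = np.asarray(q_after, dtype=float)
    if qb.shape != qa.shape:
        raise ValueError("relative-abundance vectors must have equal length")
    for q in (qb, qa):
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1 (tol 1e-9)")
    return float(2.0 * np.dot(qb, qa) / (np.dot(qb, qb) + np.dot(qa, qa)))


def weighted_matrix(
    a: np.ndarray, xstar: MetaState, scope: int | str = "meta"
) -> WeightedBipartiteMatrix:
    """Abundance-weighted interaction matrix a_ij * P*_ik * A*_jk.

    Local scope uses one network's abundances; meta scope sums the local
    products over all networks.
    """
    if a.shape != (xstar.M, xstar.N):
        raise ValueError("incidence matrix shape does not match the state")
    if scope == "meta":
        w = a * np.einsum("ik,jk->ij", xstar.P, xstar.A)
    else:
        k = int(scope)
        w = a * np.outer(xstar.P[:, k], xstar.A[:, k])
    return WeightedBipartiteMatrix(w=w, scope=scope)


def _as_weights(w) -> np.ndarray:
    return np.asarray(w.w if isinstance(w, WeightedBipartiteMatrix) else w, float)


def wnodf(w) -> float:
    """Weighted NODF nestedness (overlap and decreasing fill), in [0, 100].

    Rows and columns are ordered by decreasing fill (count of non-zero
    cells), ties broken by decreasing marginal totals.  A line pair
    contributes only when the fills strictly decrease; it then scores the
    percentage of the poorer line's non-zero cells whose value lies
    strictly below the corresponding cell of the richer line (ties score
    nothing).  The statistic averages the pair scores over all row pairs
    and column pairs, matching the quantitative-matrix NODF convention
    used by vegan/bipartite.
    """
    mat = _as_weights(w)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if (mat < 0).any():
        raise ValueError("weights must be non-negative")

    def pair_scores(m: np.ndarray) -> list[float]:
        fill = (m > 0).sum(axis=1)
        order = np.lexsort((-m.sum(axis=1), -fill))
        m, fill = m[order], fill[order]
        out = []
        for i in range(m.shape[0]):
            for j in range(i + 1, m.shape[0]):
                if fill[i] <= fill[j] or fill[j] == 0 or fill[i] == 0:
                    out.append(0.0)
                    continue
                nz = m[j] > 0
                out.append(100.0 * np.count_nonzero(m[i][nz] > m[j][nz]) / fill[j])
        return out

    scores = pair_scores(mat) + pair_scores(mat.T)
    return float(np.mean(scores))


def bipartite_modularity(
    w, rng: np.random.Generator, n_restarts: int = 20
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Barber bipartite modularity maximised by label propagation plus
    agglomeration; returns (Q, (row module labels, column module labels)).

    Stochastic search with ``n_restarts`` seeded restarts; the reported Q
    is the best found and never below the single-module value of 0.
    """
    mat = _as_weights(w)
    q, rows, cols = lpa_wb_plus(mat, rng, n_restarts=n_restarts)
    return q, (rows, cols)
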