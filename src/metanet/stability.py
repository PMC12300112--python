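"""Jacobian spectrum diagnostics at equilibrium.

Stability is read off the linearisation of the meta-network dynamics: the
real part of the leading eigenvalue of the full (S*n) x (S*n) Jacobian for
the meta-network, and of each local S x S diagonal block for the local
networks (more negative = more stable).  Dispersal contributes a negative
feedback on the diagonal (emigration plus an immigration-scaled term) and,
at high rates, splits the spectrum into two clusters on the real axis; the
gap between them is the group distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityParams
from .dispersal import DispersalStructure, flux_operator
from .dynamics import MetaState, _growth_terms

__all__ = [
    "SpectrumReport",
    "analytic_jacobian",
    "leading_eigenvalues",
    "group_distance",
]


@dataclass(frozen=True)
class SpectrumReport:
    """Eigenvalues of the meta-network Jacobian and its local blocks."""

    eigenvalues: np.ndarray
    leading_meta: float
    leading_local: np.ndarray
    leading_local_mean: float
    group_distance: float

    def __post_init__(self) -> None:
        if self.group_distance < 0:
            raise ValueError("group distance must be non-negative")
        if self.leading_meta < np.max(self.eigenvalues.real) - 1e-12:
            raise ValueError("leading_meta below an eigenvalue's real part")


def _jacobian_arrays(
    P: np.ndarray,
    A: np.ndarray,
    params: CommunityParams,
    D: DispersalStructure | None,
) -> np.ndarray:
    """Analytic Jacobian at arbitrary (not necessarily equilibrium) state.

    Network-major ordering: rows/cols [P_.1, A_.1, P_.2, A_.2, ...].  The
    derivative is taken directly on the right-hand side (quotient rule on
    the type II term), which stays finite at zero abundance where the
    rearranged diagonal form (self-regulation plus immigration over
    abundance) is undefined.
    """
    M, N, n = params.M, params.N, params.n
    S = M + N
    h = params.handling_time
    g_P, g_A = _growth_terms(P, A, params)

    den_P = 1.0 + h * (params.a @ A)            # (M, n)
    den_A = 1.0 + h * (params.a.T @ P)          # (N, n)
    B_P = np.einsum("ijk,jk->ik", params.beta_plant, A)
    B_A = np.einsum("jik,ik->jk", params.beta_animal, P)

    rp = params.r_plant * P                     # (M, n)
    ra = params.r_animal * A                    # (N, n)

    # within-network blocks, shape (rows, cols, network)
    PP = -np.einsum("ik,ijk->ijk", rp, params.alpha_plant)
    AA = -np.einsum("jk,jik->jik", ra, params.alpha_animal)
    PA = np.einsum("ik,ijk->ijk", rp, params.beta_plant / den_P[:, None, :]) - (
        rp * h * B_P / den_P**2
    )[:, None, :] * params.a[:, :, None]
    AP = np.einsum("jk,jik->jik", ra, params.beta_animal / den_A[:, None, :]) - (
        ra * h * B_A / den_A**2
    )[:, None, :] * params.a.T[:, :, None]

    J = np.zeros((n, S, n, S))
    iM = np.arange(M)
    iN = np.arange(N)
    for k in range(n):
        J[k, :M, k, :M] = PP[:, :, k]
        J[k, M:, k, M:] = AA[:, :, k]
        J[k, :M, k, M:] = PA[:, :, k]
        J[k, M:, k, :M] = AP[:, :, k]
        J[k, iM, k, iM] += g_P[:, k]
        J[k, M + iN, k, M + iN] += g_A[:, k]
    if D is not None:
        L = flux_operator(D)                    # (S, n, n)
        for s in range(S):
            J[:, s, :, s] += L[s]
    return J.reshape(n * S, n * S)


def analytic_jacobian(
    xstar: MetaState,
    params: CommunityParams,
    D: DispersalStructure | None = None,
) -> np.ndarray:
    """Full analytic Jacobian of the dynamics evaluated at ``xstar``.

    With no dispersal the matrix is block diagonal: n independent S x S
    local blocks.  At a positive equilibrium the diagonal entries reduce
    to the self-regulation term minus immigration divided by abundance,
    so scaling dispersal up drives every diagonal entry more negative
    (the negative feedback effect).
    """
    if xstar.P.shape != (params.M, params.n) or xstar.A.shape != (
        params.N,
        params.n,
    ):
        raise ValueError("state shape does not match community dimensions")
    return _jacobian_arrays(xstar.P, xstar.A, params, D)


def group_distance(eigenvalues: np.ndarray, S: int, n: int) -> float:
    """Gap between the two dispersal-induced eigenvalue groups.

    Sorting the S*n real parts in increasing order, the first group holds
    the first S*n - S values and the second the last S; the distance is
    the absolute difference between the real parts across the boundary.
    """
    eigenvalues = np.asarray(eigenvalues)
    if n < 2:
        raise ValueError("need at least 2 local networks")
    if eigenvalues.size != S * n:
        raise ValueError(f"expected {S * n} eigenvalues, got {eigenvalues.size}")
    if eigenvalues.size < S + 1:
        raise ValueError("too few eigenvalues to split into groups")
    re = np.sort(eigenvalues.real)
    cut = S * n - S
    return float(abs(re[cut - 1] - re[cut]))


def leading_eigenvalues(J: np.ndarray, S: int, n: int) -> SpectrumReport:
    """Full spectrum of the meta-network Jacobian plus local-block leaders."""
    J = np.asarray(J)
    if J.shape != (S * n, S * n):
        raise ValueError(f"expected a {S * n} x {S * n} matrix, got {J.shape}")
    if not np.isfinite(J).all():
        raise ValueError("non-finite entries in Jacobian")
    eig = np.linalg.eigvals(J)
    leading_local = np.array(
        [
            np.max(np.linalg.eigvals(J[k * S : (k + 1) * S, k * S : (k + 1) * S]).real)
            for k in range(n)
        ]
    )
    return SpectrumReport(
        eigenvalues=eig,
        leading_meta=float(np.max(eig.real)),
        leading_local=leading_local,
        leading_local_mean=float(leading_local.mean()),
        group_distance=group_distance(eig, S, n),
    )
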