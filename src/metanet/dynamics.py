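"""Coupled plant-animal ODE dynamics over a dispersal-linked meta-network.

Plant i in network k follows

    dP_ik/dt = r_ik * (1 - sum_j alpha^P_ijk P_jk
                         + sum_j a_ij beta^P_ijk A_jk
                           / (1 + h * sum_j a_ij A_jk)) * P_ik
               + dispersal flux,

with the symmetric equation for animals (plants as mutualistic partners).
Mutualistic gain saturates through a Holling type II functional response
with handling time h; dispersal is linear in density.  The state is kept
network-major (network k contributes a contiguous block of M plants then N
animals), matching the block structure used by the stability analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .community import CommunityParams
from .dispersal import DispersalStructure, flux_operator

__all__ = [
    "MetaState",
    "Trajectory",
    "rhs",
    "integrate",
    "equilibrium_abundances",
    "CONVERGENCE_RESIDUAL",
]

logger = logging.getLogger(__name__)

#: max |dX/dt| at the final time below which a run counts as converged
CONVERGENCE_RESIDUAL = 1e-6


@dataclass(frozen=True)
class MetaState:
    """Abundances of every species in every local network.

    ``P`` has shape (M, n), ``A`` shape (N, n); densities are dimensionless
    and non-negative.
    """

    P: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        if self.P.ndim != 2 or self.A.ndim != 2:
            raise ValueError("P and A must be 2-d (species x network)")
        if self.P.shape[1] != self.A.shape[1]:
            raise ValueError("P and A must span the same networks")
        if (self.P < 0).any() or (self.A < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def M(self) -> int:
        return self.P.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.P.shape[1]

    def stacked(self) -> np.ndarray:
        """All abundances as one (M + N, n) array, plants on top."""
        return np.vstack([self.P, self.A])

    def ravel(self) -> np.ndarray:
        """Flatten network-major: [P_.1, A_.1, P_.2, A_.2, ...]."""
        return self.stacked().T.ravel()

    @classmethod
    def unravel(cls, x: np.ndarray, M: int, N: int, n: int) -> "MetaState":
        Xs = x.reshape(n, M + N).T
        return cls(P=Xs[:M].copy(), A=Xs[M:].copy())

    @classmethod
    def random_uniform(
        cls, M: int, N: int, n: int, rng: np.random.Generator
    ) -> "MetaState":
        """Initial abundances drawn U(0, 1) per species and network."""
        return cls(P=rng.uniform(0, 1, (M, n)), A=rng.uniform(0, 1, (N, n)))


@dataclass(frozen=True)
class Trajectory:
    """Integration output: dense sample of states plus a convergence check."""

    times: np.ndarray
    states: list
    converged: bool
    residual: float

    @property
    def final(self) -> MetaState:
        return self.states[-1]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for t, st in zip(self.times, self.states):
            X = st.stacked()
            i, k = np.indices(X.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "time": t,
                        "species": i.ravel(),
                        "network": k.ravel(),
                        "abundance": X.ravel(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _growth_terms(
    P: np.ndarray, A: np.ndarray, params: CommunityParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-capita growth brackets r*(1 - comp + mut) for plants and animals."""
    h = params.handling_time
    comp_P = np.einsum("ijk,jk->ik", params.alpha_plant, P)
    comp_A = np.einsum("jik,ik->jk", params.alpha_animal, A)
    num_P = np.einsum("ijk,jk->ik", params.beta_plant, A)
    num_A = np.einsum("jik,ik->jk", params.beta_animal, P)
    den_P = 1.0 + h * (params.a @ A)
    den_A = 1.0 + h * (params.a.T @ P)
    g_P = params.r_plant * (1.0 - comp_P + num_P / den_P)
    g_A = params.r_animal * (1.0 - comp_A + num_A / den_A)
    return g_P, g_A


def rhs(
    state: MetaState,
    params: CommunityParams,
    D: DispersalStructure | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dP/dt, dA/dt) for a meta-network state.

    ``D=None`` removes the dispersal terms from the code path entirely.
    """
    P, A = state.P, state.A
    if P.shape != (params.M, params.n) or A.shape != (params.N, params.n):
        raise ValueError("state shape does not match community dimensions")
    if np.isnan(P).any() or np.isnan(A).any():
        raise ValueError("NaN in state")
    g_P, g_A = _growth_terms(P, A, params)
    dP = g_P * P
    dA = g_A * A
    if D is not None:
        L = flux_operator(D)
        dP = dP + np.einsum("ikl,il->ik", L[: params.M], P)
        dA = dA + np.einsum("ikl,il->ik", L[params.M :], A)
    return dP, dA


def _pack_rhs(params: CommunityParams, D: DispersalStructure | None):
    """Flat-vector rhs and analytic Jacobian closures for the solver."""
    from .stability import _jacobian_arrays  # local import: avoid cycle

    M, N, n = params.M, params.N, params.n
    L = flux_operator(D) if D is not None else None

    def f(t: float, x: np.ndarray) -> np.ndarray:
        Xs = x.reshape(n, M + N).T
        P = np.clip(Xs[:M], 0.0, None)
        A = np.clip(Xs[M:], 0.0, None)
        g_P, g_A = _growth_terms(P, A, params)
        dP = g_P * P
        dA = g_A * A
        if L is not None:
            dP = dP + np.einsum("ikl,il->ik", L[:M], P)
            dA = dA + np.einsum("ikl,il->ik", L[M:], A)
        return np.vstack([dP, dA]).T.ravel()

    def jac(t: float, x: np.ndarray) -> np.ndarray:
        Xs = x.reshape(n, M + N).T
        P = np.clip(Xs[:M], 0.0, None)
        A = np.clip(Xs[M:], 0.0, None)
        return _jacobian_arrays(P, A, params, D)

    return f, jac


def integrate(
    params: CommunityParams,
    D: DispersalStructure | None,
    x0: MetaState,
    t_end: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_eval: int = 51,
) -> Trajectory:
    """Integrate the meta-network to ``t_end`` with the LSODA solver.

    Reports a dense sample of ``n_eval`` evenly spaced states, a final
    residual max|dX/dt| and a convergence flag (residual < 1e-6).  Tiny
    negative numerical undershoots (above -10*atol) are clamped to zero;
    larger ones raise.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    M, N, n = params.M, params.N, params.n
    f, jac = _pack_rhs(params, D)
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0.ravel(),
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"LSODA failed: {sol.message}")
    floor = -10.0 * atol
    if (sol.y < floor).any():
        worst = sol.y.min()
        raise RuntimeError(
            f"integration produced a macroscopic negative abundance ({worst:.3e})"
        )
    y = np.clip(sol.y, 0.0, None)
    states = [MetaState.unravel(y[:, i], M, N, n) for i in range(y.shape[1])]
    residual = float(np.max(np.abs(f(sol.t[-1], y[:, -1]))))
    return Trajectory(
        times=sol.t,
        states=states,
        converged=residual < CONVERGENCE_RESIDUAL,
        residual=residual,
    )


def equilibrium_abundances(traj: Trajectory) -> MetaState:
    """Final state of a trajectory; warns when the run has not converged."""
    if not traj.states:
        raise ValueError("empty trajectory")
    if not traj.converged:
        warnings.warn(
            f"trajectory not converged (residual {traj.residual:.3e}); "
            "returning the final state anyway",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("non-converged trajectory: residual=%.3e", traj.residual)
    return traj.final
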