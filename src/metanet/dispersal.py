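"""Per-species dispersal-rate matrices under the 2x2 heterogeneity design.

Every species i carries an n x n rate matrix: ``rates[i, k, k]`` is the
total emigration rate of species i out of local network k, and
``rates[i, k, l]`` (k != l) is the rate at which species i moves from
network l into network k.  Emigration is exactly partitioned among the
n - 1 destinations, either evenly (homogeneous between networks) or by a
uniform random split on the simplex (heterogeneous between networks).
Heterogeneity across species is controlled by the spread sigma_d of the
per-species emigration draws around the mean mu_d.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DispersalScenario",
    "DispersalStructure",
    "SIGMA_HOMOGENEOUS",
    "SIGMA_HETEROGENEOUS",
    "build_dispersal",
    "dispersal_flux",
]

#: default spread of emigration rates across species
SIGMA_HOMOGENEOUS = 0.01
SIGMA_HETEROGENEOUS = 0.5


@dataclass(frozen=True)
class DispersalScenario:
    """One cell of the between-networks x across-species heterogeneity grid."""

    between_mode: str = "homogeneous"
    species_mode: str = "homogeneous"
    mu_d: float = 0.0
    sigma_d: float | None = None

    def __post_init__(self) -> None:
        if self.between_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown between_mode {self.between_mode!r}")
        if self.species_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown species_mode {self.species_mode!r}")
        if self.mu_d < 0:
            raise ValueError("mu_d must be non-negative")
        if self.sigma_d is None:
            default = (
                SIGMA_HOMOGENEOUS
                if self.species_mode == "homogeneous"
                else SIGMA_HETEROGENEOUS
            )
            object.__setattr__(self, "sigma_d", default)
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be non-negative")


@dataclass(frozen=True)
class DispersalStructure:
    """Stack of per-species n x n dispersal-rate matrices (shape S, n, n)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = self.rates
        if r.ndim != 3 or r.shape[1] != r.shape[2]:
            raise ValueError("rates must have shape (S, n, n)")
        if (r < 0).any():
            raise ValueError("dispersal rates must be non-negative")

    @property
    def S(self) -> int:
        return self.rates.shape[0]

    @property
    def n(self) -> int:
        return self.rates.shape[1]

    def emigration(self) -> np.ndarray:
        """Total emigration rates, shape (S, n)."""
        return np.einsum("ikk->ik", self.rates)

    def scaled(self, factor: float) -> "DispersalStructure":
        """Uniformly rescaled copy (preserves the partition identity)."""
        if factor < 0:
            raise ValueError("factor must be non-negative")
        return DispersalStructure(self.rates * factor)

    def to_csv(self, path: str | Path) -> None:
        i, k, l = np.indices(self.rates.shape)
        off = k != l
        pd.DataFrame(
            {
                "species": i[off],
                "from_network": l[off],
                "to_network": k[off],
                "rate": self.rates[off],
            }
        ).to_csv(path, index=False)


def build_dispersal(
    scenario: DispersalScenario, S: int, n: int, rng: np.random.Generator
) -> DispersalStructure:
    """Draw a dispersal structure for S species over n local networks.

    Emigration rates are Normal(mu_d, sigma_d) truncated at zero,
    independent per (species, network).  Under the homogeneous
    between-networks mode each rate is split evenly over the n - 1
    destinations; under the heterogeneous mode the split weights are a
    flat Dirichlet draw, redrawn per species and source network.
    """
    if n < 2:
        raise ValueError("need at least 2 local networks")
    emi = rng.normal(scenario.mu_d, scenario.sigma_d, (S, n))
    np.clip(emi, 0.0, None, out=emi)

    rates = np.zeros((S, n, n))
    if scenario.between_mode == "homogeneous":
        shares = np.broadcast_to(emi[:, None, :] / (n - 1), (S, n, n)).copy()
    else:
        w = rng.dirichlet(np.ones(n - 1), size=(S, n))  # (S, source, n-1)
        shares = np.zeros((S, n, n))
        for k in range(n):
            dest = [l for l in range(n) if l != k]
            shares[:, dest, k] = emi[:, k, None] * w[:, k, :]
    if scenario.between_mode == "homogeneous":
        # zero the would-be self-share before installing the diagonal
        for k in range(n):
            shares[:, k, k] = 0.0
    rates[:] = shares
    idx = np.arange(n)
    rates[:, idx, idx] = emi
    return DispersalStructure(rates)


def dispersal_flux(X: np.ndarray, D: DispersalStructure) -> np.ndarray:
    """Net dispersal flux for every species in every network, shape (S, n).

    flux[i, k] = -rates[i,k,k] * X[i,k] + sum_{l != k} rates[i,k,l] * X[i,l];
    sums to zero over networks for each species (mass is moved, not made).
    """
    if X.shape != (D.S, D.n):
        raise ValueError(f"state shape {X.shape} != ({D.S}, {D.n})")
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    return np.einsum("ikl,il->ik", flux_operator(D), X)


def flux_operator(D: DispersalStructure) -> np.ndarray:
    """Per-species linear operators L with flux_i = L_i @ X_i (shape S, n, n).

    Off-diagonals are the immigration rates; diagonals are the negated
    emigration totals.
    """
    L = D.rates.copy()
    idx = np.arange(D.n)
    L[:, idx, idx] = -D.rates[:, idx, idx]
    return L
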