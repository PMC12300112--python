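"""Sampling of the bipartite interaction structure and dynamical parameters.

A community holds M plant species and N animal (pollinator) species
replicated over n local networks.  The plant-animal incidence matrix ``a``
is binary with fixed connectance; growth rates, competition strengths and
mutualism benefit strengths are drawn independently for every local
network, so each patch realises its own parameterisation of the same
interaction topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityConfig",
    "CommunityParams",
    "sample_interaction_matrix",
    "sample_parameters",
    "sample_community",
    "competition_only",
]


@dataclass(frozen=True)
class CommunityConfig:
    """Configuration of a meta-community and its parameter distributions.

    Defaults follow the standard simulation setting: 30 plants and 20
    animals in 10 local networks at connectance 0.2; growth rates
    log-normal LN(1, 0.1); competition and mutualism strengths drawn from
    N(0, 0.05); self-regulation magnitude 1; handling time 0.1.
    """

    M: int = 30
    N: int = 20
    n: int = 10
    connectance: float = 0.2
    growth_logmean: float = 1.0
    growth_logsd: float = 0.1
    comp_mean: float = 0.0
    comp_sd: float = 0.05
    mut_mean: float = 0.0
    mut_sd: float = 0.05
    self_reg_magnitude: float = 1.0
    handling_time: float = 0.1
    nonnegative_benefits: bool = True
    truncate_nonnegative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be at least 1")
        if self.n < 2:
            raise ValueError("need at least 2 local networks")
        if not 0.0 < self.connectance <= 1.0:
            raise ValueError("connectance must lie in (0, 1]")
        if self.handling_time < 0:
            raise ValueError("handling_time must be non-negative")
        if self.self_reg_magnitude <= 0:
            raise ValueError("self_reg_magnitude must be positive")

    @property
    def S(self) -> int:
        """Total species count M + N."""
        return self.M + self.N

    # -- flat key-value (de)serialisation ---------------------------------

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "CommunityConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass(frozen=True)
class CommunityParams:
    """All sampled per-network parameters plus the binary incidence matrix.

    Array shapes: ``a`` (M, N); growth rates (M, n) / (N, n); competition
    strengths (M, M, n) / (N, N, n) with the self-regulation magnitude on
    each diagonal slice; benefit strengths (M, N, n) for plants and
    (N, M, n) for animals, zero wherever ``a`` has no link.
    """

    a: np.ndarray
    r_plant: np.ndarray
    r_animal: np.ndarray
    alpha_plant: np.ndarray
    alpha_animal: np.ndarray
    beta_plant: np.ndarray
    beta_animal: np.ndarray
    handling_time: float

    @property
    def M(self) -> int:
        return self.a.shape[0]

    @property
    def N(self) -> int:
        return self.a.shape[1]

    @property
    def n(self) -> int:
        return self.r_plant.shape[1]

    @property
    def S(self) -> int:
        return self.M + self.N

    def __post_init__(self) -> None:
        M, N = self.a.shape
        n = self.r_plant.shape[1]
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("incidence matrix must be 0/1 valued")
        if self.r_plant.shape != (M, n) or self.r_animal.shape != (N, n):
            raise ValueError("growth-rate array shapes do not match (M, N, n)")
        if (self.r_plant <= 0).any() or (self.r_animal <= 0).any():
            raise ValueError("growth rates must be strictly positive")
        if self.alpha_plant.shape != (M, M, n) or self.alpha_animal.shape != (N, N, n):
            raise ValueError("competition array shapes do not match")
        if self.beta_plant.shape != (M, N, n) or self.beta_animal.shape != (N, M, n):
            raise ValueError("benefit array shapes do not match")
        mask = self.a == 0
        if self.beta_plant[mask].any() or self.beta_animal[mask.T].any():
            raise ValueError("benefit strengths must vanish where a = 0")

    def to_csv_dir(self, outdir: str | Path) -> None:
        """Dump every array in long format (one CSV per array) for audit."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _long(self.a[:, :, None], "plant", "animal").to_csv(
            outdir / "a.csv", index=False
        )
        _long(self.r_plant[:, None, :], "plant", "_").drop(columns="_").to_csv(
            outdir / "r_plant.csv", index=False
        )
        _long(self.r_animal[:, None, :], "animal", "_").drop(columns="_").to_csv(
            outdir / "r_animal.csv", index=False
        )
        for name, arr, ri, ci in (
            ("alpha_plant", self.alpha_plant, "plant_i", "plant_j"),
            ("alpha_animal", self.alpha_animal, "animal_i", "animal_j"),
            ("beta_plant", self.beta_plant, "plant", "animal"),
            ("beta_animal", self.beta_animal, "animal", "plant"),
        ):
            _long(arr, ri, ci).to_csv(outdir / f"{name}.csv", index=False)


def _long(arr: np.ndarray, row: str, col: str) -> pd.DataFrame:
    i, j, k = np.indices(arr.shape)
    return pd.DataFrame(
        {
            row: i.ravel(),
            col: j.ravel(),
            "network_k": k.ravel(),
            "value": arr.ravel(),
        }
    )


def sample_interaction_matrix(
    M: int, N: int, connectance: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a binary M x N incidence matrix with an exact link count.

    Exactly ``round(connectance * M * N)`` cells are set to 1, placed
    uniformly at random without replacement, so the realised density is
    identical for every seed.
    """
    if not 0.0 < connectance <= 1.0:
        raise ValueError("connectance must lie in (0, 1]")
    n_links = int(round(connectance * M * N))
    if n_links == 0:
        raise ValueError("connectance too small: rounds to zero links")
    flat = rng.choice(M * N, size=n_links, replace=False)
    a = np.zeros(M * N, dtype=int)
    a[flat] = 1
    return a.reshape(M, N)


def sample_parameters(
    config: CommunityConfig, a: np.ndarray, rng: np.random.Generator
) -> CommunityParams:
    """Sample all per-network rates and strengths for a given topology.

    Growth rates are log-normal (strictly positive by construction);
    competition and benefit strengths are normal draws, independent across
    species pairs and local networks.  Benefit strengths are masked to zero
    where the incidence matrix has no link, and each competition slice gets
    the self-regulation magnitude on its diagonal.
    """
    M, N, n = config.M, config.N, config.n
    if a.shape != (M, N):
        raise ValueError(f"incidence matrix shape {a.shape} != ({M}, {N})")

    r_plant = rng.lognormal(config.growth_logmean, config.growth_logsd, (M, n))
    r_animal = rng.lognormal(config.growth_logmean, config.growth_logsd, (N, n))

    alpha_plant = rng.normal(config.comp_mean, config.comp_sd, (M, M, n))
    alpha_animal = rng.normal(config.comp_mean, config.comp_sd, (N, N, n))
    beta_plant = rng.normal(config.mut_mean, config.mut_sd, (M, N, n))
    beta_animal = rng.normal(config.mut_mean, config.mut_sd, (N, M, n))

    if config.truncate_nonnegative:
        alpha_plant = np.clip(alpha_plant, 0.0, None)
        alpha_animal = np.clip(alpha_animal, 0.0, None)
    if config.nonnegative_benefits or config.truncate_nonnegative:
        # a mutualistic "benefit" is non-negative by definition; negative
        # normal draws are censored at zero rather than kept as costs
        beta_plant = np.clip(beta_plant, 0.0, None)
        beta_animal = np.clip(beta_animal, 0.0, None)

    # stabilising convention: +magnitude inside the (1 - sum alpha*X) bracket
    idx = np.arange(M)
    alpha_plant[idx, idx, :] = config.self_reg_magnitude
    idx = np.arange(N)
    alpha_animal[idx, idx, :] = config.self_reg_magnitude

    beta_plant = beta_plant * a[:, :, None]
    beta_animal = beta_animal * a.T[:, :, None]

    return CommunityParams(
        a=a,
        r_plant=r_plant,
        r_animal=r_animal,
        alpha_plant=alpha_plant,
        alpha_animal=alpha_animal,
        beta_plant=beta_plant,
        beta_animal=beta_animal,
        handling_time=config.handling_time,
    )


def sample_community(
    config: CommunityConfig, rng: np.random.Generator | None = None
) -> CommunityParams:
    """Convenience wrapper: topology plus parameters from one seeded stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a = sample_interaction_matrix(config.M, config.N, config.connectance, rng)
    return sample_parameters(config, a, rng)


def competition_only(params: CommunityParams) -> CommunityParams:
    """Copy of the community with every mutualism benefit set to zero.

    Leaves topology, growth rates and competition strengths untouched;
    idempotent.
    """
    return replace(
        params,
        beta_plant=np.zeros_like(params.beta_plant),
        beta_animal=np.zeros_like(params.beta_animal),
    )
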