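"""Scenario sweep orchestration: the eight interaction x dispersal cells.

The experimental design crosses interaction type (competition-mutualism
C+M vs competition-only C) with dispersal heterogeneity between local
networks (HtN vs HmN) and across species (HtS vs HmS), evaluated over a
logarithmic grid of mean dispersal rates.  Each replicate community is
sampled once and shared across scenarios and grid points, so contrasts
are paired; the zero-dispersal baseline (needed for the temporal
similarity and the Gini reference) is integrated once per community and
interaction type and reused.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from .community import (
    CommunityConfig,
    CommunityParams,
    competition_only,
    sample_community,
)
from .dispersal import (
    SIGMA_HETEROGENEOUS,
    SIGMA_HOMOGENEOUS,
    DispersalScenario,
    DispersalStructure,
    build_dispersal,
)
from .dynamics import MetaState, Trajectory, equilibrium_abundances, integrate
from .stability import analytic_jacobian, leading_eigenvalues

__all__ = [
    "Scenario",
    "SweepSpec",
    "ALL_SCENARIOS",
    "ALL_METRICS",
    "default_grid",
    "run_cell",
    "run_sweep",
]

logger = logging.getLogger(__name__)

ALL_METRICS = frozenset(
    {"abundance", "gini", "similarity", "nestedness", "modularity", "spectrum"}
)


@dataclass(frozen=True)
class Scenario:
    """One of the eight design cells of the interaction x dispersal grid."""

    interaction: str = "competition_mutualism"
    between_mode: str = "homogeneous"
    species_mode: str = "homogeneous"

    def __post_init__(self) -> None:
        if self.interaction not in ("competition_mutualism", "competition_only"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        DispersalScenario(self.between_mode, self.species_mode)  # validates

    @property
    def sigma_d(self) -> float:
        return (
            SIGMA_HOMOGENEOUS
            if self.species_mode == "homogeneous"
            else SIGMA_HETEROGENEOUS
        )

    @property
    def label(self) -> str:
        inter = "C+M" if self.interaction == "competition_mutualism" else "C"
        betw = "HmN" if self.between_mode == "homogeneous" else "HtN"
        spec = "HmS" if self.species_mode == "homogeneous" else "HtS"
        return f"{inter}/{betw}/{spec}"

    def dispersal(self, mu_d: float) -> DispersalScenario:
        return DispersalScenario(self.between_mode, self.species_mode, mu_d)


ALL_SCENARIOS: tuple[Scenario, ...] = tuple(
    Scenario(i, b, s)
    for i, b, s in itertools.product(
        ("competition_mutualism", "competition_only"),
        ("homogeneous", "heterogeneous"),
        ("homogeneous", "heterogeneous"),
    )
)


def default_grid() -> np.ndarray:
    """The 30-point mean-dispersal grid: {0} plus e^-4 .. e^3 in steps e^0.25."""
    return np.concatenate([[0.0], np.exp(-4.0 + 0.25 * np.arange(29))])


@dataclass(frozen=True)
class SweepSpec:
    """Full design of a sweep: scenarios x grid x replicate communities."""

    config: CommunityConfig = CommunityConfig()
    scenarios: tuple[Scenario, ...] = ALL_SCENARIOS
    mu_d_grid: tuple[float, ...] = tuple(default_grid())
    replicates: int = 5
    base_seed: int = 0
    metrics: frozenset[str] = ALL_METRICS
    t_end: float = 50.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        grid = np.asarray(self.mu_d_grid)
        if (grid < 0).any() or not (np.diff(grid) >= 0).all():
            raise ValueError("mu_d_grid must be non-negative and sorted")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        unknown = set(self.metrics) - ALL_METRICS
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "scenarios": [s.label for s in self.scenarios],
            "mu_d_grid": list(map(float, self.mu_d_grid)),
            "replicates": self.replicates,
            "base_seed": self.base_seed,
            "metrics": sorted(self.metrics),
            "t_end": self.t_end,
            "rtol": self.rtol,
            "atol": self.atol,
        }


def _zero_dispersal(S: int, n: int) -> DispersalStructure:
    return DispersalStructure(np.zeros((S, n, n)))


def run_cell(
    scenario: Scenario,
    mu_d: float,
    community: CommunityParams,
    x0: MetaState,
    seed: int,
    baseline: Trajectory | None = None,
    metrics: frozenset[str] = ALL_METRICS,
    t_end: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> mx.MetricsRecord:
    """Run one (scenario, mu_d) cell and compute the selected metrics.

    ``community`` always carries the full competition-mutualism
    parameterisation; competition-only scenarios zero the benefits here.
    ``mu_d = 0`` means no dispersal at all (the baseline condition), so the
    temporal similarity of that cell is 1 by construction.  The baseline
    trajectory can be passed in to avoid re-integrating it per grid point.
    """
    params = (
        community
        if scenario.interaction == "competition_mutualism"
        else competition_only(community)
    )
    S, n = params.S, params.n
    rng = np.random.default_rng(seed)
    if mu_d == 0.0:
        D = _zero_dispersal(S, n)
    else:
        D = build_dispersal(scenario.dispersal(mu_d), S, n, rng)

    if baseline is None:
        baseline = integrate(params, None, x0, t_end=t_end, rtol=rtol, atol=atol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x_base = equilibrium_abundances(baseline)

    if mu_d == 0.0:
        traj = baseline
    else:
        traj = integrate(params, D, x0, t_end=t_end, rtol=rtol, atol=atol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        xstar = equilibrium_abundances(traj)

    rec: dict = {
        "scenario": scenario.label,
        "mu_d": float(mu_d),
        "seed": int(seed),
        "residual": traj.residual,
        "converged": traj.converged,
    }
    if "abundance" in metrics:
        rec["total_abundance"] = mx.total_abundance(xstar)
    if "gini" in metrics:
        rec["gini_meta"] = mx.gini(xstar.stacked().ravel())
        rec["gini_local_mean"] = mx.gini_local_mean(xstar)
    if "similarity" in metrics:
        rec["mh_spatial"] = mx.morisita_horn_spatial(xstar)
        rec["mh_temporal"] = mx.morisita_horn_temporal(
            mx.meta_relative_abundance(x_base), mx.meta_relative_abundance(xstar)
        )
    if "nestedness" in metrics or "modularity" in metrics:
        w_meta = mx.weighted_matrix(params.a, xstar, "meta")
        w_local = [mx.weighted_matrix(params.a, xstar, k) for k in range(n)]
    if "nestedness" in metrics:
        rec["wnodf_meta"] = mx.wnodf(w_meta)
        rec["wnodf_local_mean"] = float(np.mean([mx.wnodf(w) for w in w_local]))
    if "modularity" in metrics:
        rec["modularity_meta"] = mx.bipartite_modularity(w_meta, rng)[0]
        rec["modularity_local_mean"] = float(
            np.mean([mx.bipartite_modularity(w, rng)[0] for w in w_local])
        )
    if "spectrum" in metrics:
        J = analytic_jacobian(xstar, params, D)
        rep = leading_eigenvalues(J, S, n)
        rec["leading_meta"] = rep.leading_meta
        rec["leading_local_mean"] = rep.leading_local_mean
        rec["group_distance"] = rep.group_distance
    return mx.MetricsRecord(**rec)


def run_sweep(spec: SweepSpec, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run the full design and return one tidy row per cell.

    Every replicate community (parameters and initial abundances) is
    shared across scenarios and grid points.  Per-cell failures are
    caught, flagged in the ``error`` column and reported at the end rather
    than aborting the sweep.  With ``outdir`` set, rows are flushed
    incrementally to ``records.csv`` next to a JSON run manifest.
    """
    cfg = spec.config
    root = np.random.SeedSequence(spec.base_seed)
    rep_seqs = root.spawn(spec.replicates)

    out_csv = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(spec.manifest(), indent=2))
        out_csv = outdir / "records.csv"
        if out_csv.exists():
            out_csv.unlink()

    rows: list[dict] = []
    failures = 0
    for rep, seq in enumerate(rep_seqs):
        comm_seed, x0_seed, cell_root = seq.spawn(3)
        community = sample_community(cfg, np.random.default_rng(comm_seed))
        x0 = MetaState.random_uniform(
            cfg.M, cfg.N, cfg.n, np.random.default_rng(x0_seed)
        )
        baselines = {
            inter: integrate(
                community if inter == "competition_mutualism"
                else competition_only(community),
                None,
                x0,
                t_end=spec.t_end,
                rtol=spec.rtol,
                atol=spec.atol,
            )
            for inter in {s.interaction for s in spec.scenarios}
        }
        n_cells = len(spec.scenarios) * len(spec.mu_d_grid)
        cell_seeds = cell_root.spawn(n_cells)
        for idx, (scen, mu_d) in enumerate(
            itertools.product(spec.scenarios, spec.mu_d_grid)
        ):
            seed = int(cell_seeds[idx].generate_state(1)[0] % (2**31))
            t0 = time.perf_counter()
            try:
                rec = run_cell(
                    scen,
                    mu_d,
                    community,
                    x0,
                    seed,
                    baseline=baselines[scen.interaction],
                    metrics=spec.metrics,
                    t_end=spec.t_end,
                    rtol=spec.rtol,
                    atol=spec.atol,
                )
                row = rec.to_dict()
            except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
                failures += 1
                logger.error("cell %s mu_d=%.4g rep=%d failed: %s",
                             scen.label, mu_d, rep, exc)
                row = mx.MetricsRecord(
                    scenario=scen.label, mu_d=float(mu_d), seed=seed, error=str(exc)
                ).to_dict()
            row["replicate"] = rep
            rows.append(row)
            logger.info(
                "cell %s mu_d=%.4g rep=%d done in %.2fs (residual=%s)",
                scen.label, mu_d, rep, time.perf_counter() - t0,
                row.get("residual"),
            )
            if out_csv is not None:
                pd.DataFrame([row]).to_csv(
                    out_csv, mode="a", header=not out_csv.exists(), index=False
                )
    if failures:
        logger.warning("%d of %d cells failed; see the error column", failures, len(rows))
    return pd.DataFrame(rows)
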