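"""Simulate one meta-network cell and read off its metrics.

Builds a standard community (30 plants, 20 animals, 10 local networks at
connectance 0.2), couples the networks with homogeneous dispersal at mean
rate 1.0, integrates to equilibrium and prints every metric the simulator
computes for that cell.
"""

import numpy as np

from metanet import (
    ALL_SCENARIOS,
    CommunityConfig,
    MetaState,
    run_cell,
    sample_community,
)

cfg = CommunityConfig(M=30, N=20, n=10, connectance=0.2, seed=1)
rng = np.random.default_rng(cfg.seed)
community = sample_community(cfg, rng)
x0 = MetaState.random_uniform(cfg.M, cfg.N, cfg.n, rng)

scenario = ALL_SCENARIOS[0]  # competition-mutualism, fully homogeneous dispersal
record = run_cell(scenario, mu_d=1.0, community=community, x0=x0, seed=7)

for key, value in record.to_dict().items():
    if value is not None:
        print(f"{key:22s} {value}")

print(
    "\nReading: total_abundance sums all 500 equilibrium densities;"
    "\ngini_* measure abundance inequality (0 = perfectly even);"
    "\nmh_spatial compares the 10 local networks' compositions (1 = identical)"
    "\nand mh_temporal compares the meta-network with its zero-dispersal"
    "\nbaseline; wnodf_* are nestedness on the 0-100 scale; modularity_* are"
    "\nBarber Q; leading_* are Jacobian leading eigenvalues (more negative ="
    "\nmore stable) and group_distance is the dispersal-induced spectral gap."
)
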