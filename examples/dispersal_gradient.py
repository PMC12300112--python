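"""Stability along a dispersal gradient.

Integrates the same community at increasing mean dispersal rates and
prints the meta-network and mean local leading eigenvalues plus the
eigenvalue group distance: local stability strengthens roughly linearly
with dispersal (the negative feedback effect), while the meta-network
leading eigenvalue plateaus once the spectrum splits into two groups and
the group distance starts growing in step with the rate.
"""

import numpy as np

from metanet import (
    ALL_SCENARIOS,
    CommunityConfig,
    MetaState,
    integrate,
    run_cell,
    sample_community,
)

cfg = CommunityConfig(M=30, N=20, n=10, connectance=0.2, seed=1)
rng = np.random.default_rng(cfg.seed)
community = sample_community(cfg, rng)
x0 = MetaState.random_uniform(cfg.M, cfg.N, cfg.n, rng)
baseline = integrate(community, None, x0)

scenario = ALL_SCENARIOS[0]
print(f"scenario {scenario.label}")
print(f"{'mu_d':>8} {'leading_meta':>13} {'leading_local':>14} {'group_dist':>11}")
for mu_d in np.exp(np.arange(-4.0, 3.5, 1.0)):
    rec = run_cell(
        scenario, mu_d, community, x0, seed=7, baseline=baseline,
        metrics=frozenset({"spectrum"}),
    )
    print(
        f"{mu_d:8.3f} {rec.leading_meta:13.3f} "
        f"{rec.leading_local_mean:14.3f} {rec.group_distance:11.3f}"
    )

print(
    "\nReading: leading_local keeps falling as dispersal strengthens the"
    "\nJacobian diagonal, while leading_meta saturates; past the stability"
    "\nplateau the extra dispersal only widens the spectral gap (group_dist)."
)
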