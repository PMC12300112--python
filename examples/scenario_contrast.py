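"""Mutualism versus pure competition at strong dispersal.

Runs the competition-mutualism (C+M) and competition-only (C) versions of
the same community at a high homogeneous dispersal rate and contrasts
stability, abundance, unevenness and nestedness - the orderings the
dispersal-coupled mutualism model produces.
"""

import numpy as np

from metanet import CommunityConfig, MetaState, Scenario, run_cell, sample_community

cfg = CommunityConfig(M=30, N=20, n=10, connectance=0.2, seed=1)
rng = np.random.default_rng(cfg.seed)
community = sample_community(cfg, rng)
x0 = MetaState.random_uniform(cfg.M, cfg.N, cfg.n, rng)

mu_d = float(np.exp(2))
records = {}
for interaction in ("competition_mutualism", "competition_only"):
    scenario = Scenario(interaction, "homogeneous", "homogeneous")
    records[scenario.label] = run_cell(
        scenario, mu_d, community, x0, seed=7,
        metrics=frozenset({"abundance", "gini", "nestedness", "spectrum"}),
    )

print(f"mu_d = {mu_d:.3f}")
print(f"{'':16}{'C+M/HmN/HmS':>14}{'C/HmN/HmS':>14}")
for field in ("leading_meta", "total_abundance", "gini_meta", "wnodf_meta"):
    a = getattr(records["C+M/HmN/HmS"], field)
    b = getattr(records["C/HmN/HmS"], field)
    print(f"{field:16}{a:14.4f}{b:14.4f}")

print(
    "\nReading: with net-positive mutualistic benefits the C+M community is"
    "\nmore stable (more negative leading eigenvalue), carries more total"
    "\nabundance and is more nested than the same community stripped of"
    "\nmutualism; the Gini difference between the two is small."
)
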