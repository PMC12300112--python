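"""A reduced eight-scenario sweep with tidy output.

Runs every design cell (interaction type x dispersal heterogeneity
between networks x across species) over a short dispersal-rate grid with
two replicate communities, then prints per-scenario means of the
similarity and stability metrics.  Swap in ``default_grid()`` and more
replicates for the full design; pass ``outdir=`` to stream records to CSV.
"""

import numpy as np

from metanet import ALL_SCENARIOS, CommunityConfig, SweepSpec, run_sweep

spec = SweepSpec(
    config=CommunityConfig(M=30, N=20, n=10, connectance=0.2, seed=0),
    scenarios=ALL_SCENARIOS,
    mu_d_grid=tuple(np.exp([-4.0, -1.5, 1.0, 3.0])),
    replicates=2,
    base_seed=0,
    metrics=frozenset({"abundance", "similarity", "spectrum"}),
)
df = run_sweep(spec)

summary = (
    df.groupby("scenario")[
        ["total_abundance", "mh_spatial", "mh_temporal", "leading_meta"]
    ]
    .mean()
    .round(4)
)
print(summary.to_string())
print(
    f"\n{len(df)} cells: 8 scenarios x {len(spec.mu_d_grid)} rates x "
    f"{spec.replicates} replicates."
    "\nReading: HtN rows (heterogeneous dispersal between networks) show the"
    "\nlower abundance and spatial similarity; C+M rows are the more stable"
    "\nand more abundant counterparts of the matched C rows."
)
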