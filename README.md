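# metanet

Simulator for **plant–pollinator meta-networks**: groups of local
ecological networks coupled by species dispersal.  Each local network
hosts `M` plant and `N` animal species interacting through intra-guild
competition and saturating (Holling type II) mutualism; linear
emigration/immigration links the `n` local networks.  The package is for
theoretical ecologists studying how mutualism and dispersal
heterogeneity — between local networks and across species — shape the
stability, biodiversity and structure of spatially fragmented
communities.

## Model

The abundance `P_ik` of plant `i` in local network `k` (and symmetrically
`A_jk` for animals) follows

```
dP_ik/dt = r_ik (1 − Σ_j α^P_ijk P_jk + Σ_j a_ij β^P_ijk A_jk / (1 + h Σ_j a_ij A_jk)) P_ik
           − Σ_{l≠k} d^P_ilk P_ik + Σ_{l≠k} d^P_ikl P_il
```

where `a` is a binary plant×animal incidence matrix at fixed connectance,
`α` are competition strengths (self-regulation on the diagonal), `β ≥ 0`
are mutualistic benefit strengths, `h` is the handling time, and the `d`
terms are per-species emigration and immigration rates.  Setting all
`β = 0` gives the competition-only counterpart.  Dispersal heterogeneity
is controlled two ways: *between networks* (a species' emigration is
split evenly among destinations, or randomly on the simplex) and *across
species* (the spread `σ_d` of emigration rates around the mean `μ_d`).

From the equilibrium at `t = 50` the package computes:

- **stability** — leading eigenvalue of the full `Sn × Sn` analytic
  Jacobian and of each local `S × S` block (more negative = more stable),
  plus the *group distance*, the gap between the two dispersal-induced
  eigenvalue clusters on the real axis;
- **structure** — total abundance, Gini unevenness, Morisita–Horn
  compositional similarity (spatial: among local networks; temporal:
  against the zero-dispersal baseline), abundance-weighted interaction
  matrices, weighted NODF nestedness, and Barber bipartite modularity
  maximised by label propagation with agglomeration.

## Worked example

`examples/scenario_contrast.py` contrasts the same community with and
without mutualism at a high homogeneous dispersal rate:

```
mu_d = 7.389
                   C+M/HmN/HmS     C/HmN/HmS
leading_meta           -2.5480       -2.4068
total_abundance       541.6206      508.3690
gini_meta               0.0591        0.0553
wnodf_meta             11.2465       10.3851
```

The competition–mutualism community (C+M) is more stable (leading
eigenvalue −2.55 vs −2.41), carries ~7 % more total abundance and is more
nested (weighted NODF 11.2 vs 10.4) than its competition-only (C)
counterpart; Gini unevenness differs only marginally.  The other scripts
in `examples/` walk through a single cell (`single_cell.py`), the
stability mechanisms along a dispersal gradient
(`dispersal_gradient.py`), and a reduced eight-scenario sweep
(`full_sweep.py`).

A thin CLI wraps the same machinery:

```sh
metanet simulate --mu-d 1.0 --scenario "C+M/HmN/HmS"
metanet sweep --replicates 3 --outdir runs/
metanet metrics equilibrium.csv incidence.csv
```

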