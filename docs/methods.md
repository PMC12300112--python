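# Methods

## Model

The simulator couples `n` local plant–pollinator networks through
dispersal.  Local network `k` hosts `M` plants and `N` animals whose
densities follow

    dP_ik/dt = r_ik (1 − Σ_j α^P_ijk P_jk
                       + Σ_j a_ij β^P_ijk A_jk / (1 + h Σ_j a_ij A_jk)) P_ik
               − Σ_{l≠k} d^P_ilk P_ik + Σ_{l≠k} d^P_ikl P_il

with the mirror equation for animals (plants as mutualistic partners).
Assumptions: interactions are local (only dispersal crosses network
boundaries); all local networks are potentially reachable from all others
(spatially implicit, fully connected landscape); mutualistic gain
saturates with partner density through a type II functional response with
a handling time shared by all species; dispersal is linear in density
with no cost, distance dependence or density dependence; dynamics are
deterministic (no demographic or environmental noise).

The intraspecific term in the growth bracket is `−P_ik` (self-regulation
magnitude 1 with the stabilising sign), so an isolated species follows
logistic growth to carrying capacity 1.  The convention makes the
diagonal of the equilibrium Jacobian `−r_ik α_iik P_ik − (1/P_ik) Σ_l
d_ikl P_il`: strictly negative, and increasingly so as dispersal rates
grow (the negative feedback effect).

## Sampled communities (the data generator)

A community is sampled once per replicate and shared across scenarios and
dispersal rates, so scenario contrasts are paired:

| parameter | meaning | default | units |
|---|---|---|---|
| `M`, `N`, `n` | plants, animals, local networks | 30, 20, 10 | counts |
| `connectance` | realised link fraction of `a` | 0.2 | – |
| `r` | growth rates | LN(1, 0.1) per species & network | 1/time |
| `α` (off-diag) | competition strengths | N(0, 0.05) per pair & network | – |
| `α_ii` | self-regulation magnitude | 1 | – |
| `β` | mutualistic benefits | N(0, 0.05), censored at 0, masked by `a` | – |
| `h` | handling time | 0.1 | time |
| `X(0)` | initial abundances | U(0, 1) per species & network | – |

Notes on the open choices:

- **Exact link count.** The incidence matrix places exactly
  `round(C·M·N)` links uniformly at random, so density is identical for
  every seed; no guarantee every species has a partner.
- **Censored benefits.** A mutualistic "benefit" is non-negative by
  definition; negative normal draws are censored at zero
  (`nonnegative_benefits=True`).  With raw mean-zero draws the mutualism
  term is pure noise and the competition–mutualism model becomes
  statistically indistinguishable from the competition-only model — none
  of the mutualism effects (greater stability, abundance, nestedness)
  can arise.  Competition strengths keep the stated mean-zero law:
  negative values simply act as weak facilitation.  A separate
  `truncate_nonnegative` flag (off by default) censors both families.
- **Independent per-network draws.** Growth, competition and benefit
  values are drawn independently for each local network (the subscript
  `k`), which makes local networks genuinely different habitats.  The
  cost is a floor of ≈0.93 on cross-network compositional similarity at
  weak dispersal; sharing draws across networks would push that floor to
  1 but flattens the meta-network stability response to dispersal, so it
  was rejected.

## Dispersal structures

Each species carries an `n×n` rate matrix: the diagonal holds total
emigration out of each network, off-diagonals the per-destination rates,
and emigration is exactly partitioned among the `n−1` destinations.
Emigration rates are `Normal(μ_d, σ_d)` truncated at zero — negative
draws are physically meaningless and occur mainly at `μ_d = e⁻⁴` with
`σ_d = 0.5`.  Heterogeneity across species is `σ_d`: 0.01 (homogeneous)
or 0.5 (heterogeneous).  Heterogeneity between networks is the partition:
an even `d/(n−1)` split, or weights drawn from a flat Dirichlet on the
`(n−1)`-simplex — the maximum-entropy reading of "randomly partitioned" —
redrawn per species and source network.  `μ_d = 0` in the experiment
design means no dispersal at all (the baseline condition), not a
truncated-normal draw around zero.

## Integration and equilibrium

The coupled system (`S·n` equations, network-major ordering) is
integrated with LSODA (SciPy `solve_ivp`), supplied with the analytic
Jacobian, to `t = 50` at `rtol = 1e−8`, `atol = 1e−10`; these tolerances
hold the reported metrics stable to ~6 significant digits (halving them
changes equilibria by <1e−5 relative).  Equilibrium is the state at
`t = 50`, with an explicit residual check: the run is flagged converged
when max|dX/dt| < 1e−6, and downstream consumers warn when it is not.
Tiny negative undershoots (above −10·atol) are clamped to zero; larger
ones abort with a diagnostic.  The growth and emigration terms vanish at
zero abundance and immigration is non-negative, so trajectories from
non-negative initial conditions stay non-negative up to solver error.

## Stability diagnostics

The Jacobian is assembled analytically (quotient rule on the type II
term); central finite differences of the right-hand side serve as a test
oracle only.  At zero abundance the direct partial derivative is used —
the rearranged diagonal form with `1/P_ik` is an algebraic identity valid
only at positive equilibrium.  Reported diagnostics: leading eigenvalue
of the full matrix (meta-network stability), leading eigenvalue of each
diagonal `S×S` block and their mean (local stability), and the group
distance — with real parts sorted increasingly, the absolute gap between
the `(Sn−S)`-th and `(Sn−S+1)`-th values, which measures the
dispersal-induced split of the spectrum into a shifted group of `Sn−S`
values and a residual group of `S`.  Sorting uses real parts; ties cannot
change the gap.

## Structure metrics

- **Gini** follows the ranked form `G = (1/S)(S+1 − 2Σ(S+1−i)X_i/ΣX_i)`;
  0 for perfect evenness, bounded by `1 − 1/S`.  Meta-network unevenness
  pools all `S·n` equilibrium values ("all species across all local
  networks"); local unevenness averages per-network Gini values.
  Species at zero abundance are retained.
- **Morisita–Horn.**  Spatial similarity is the multiple-assemblage
  index over the `n` per-network relative-abundance vectors; temporal
  similarity compares the pooled meta-network relative abundances with
  the same community integrated without dispersal (same parameters, same
  initial conditions, zero rates).
- **Weighted matrices.**  Local: `a_ij P*_ik A*_jk`; meta: the sum over
  networks.
- **Weighted NODF** follows the quantitative-matrix convention of
  vegan/bipartite: lines ordered by decreasing fill (ties by marginal
  total), pairs contribute only under strictly decreasing fill, and a
  contributing pair scores the percentage of the poorer line's non-zero
  cells strictly below the richer line's corresponding cells.  Ties in
  cell values score nothing.  Degenerate (single-row/column) matrices are
  rejected.
- **Barber modularity** is maximised by label propagation plus greedy
  module agglomeration with propagation after each merge.  Restarts (20
  by default) vary the initial module count coarse-to-fine, and a node
  repelled by every module defects to a fresh singleton; the best Q over
  restarts is kept and is never below the single-module value 0.  On all
  bipartite matrices with ≤6 nodes tested, the search matches exhaustive
  enumeration over partitions.

## Experiment design

Eight scenarios cross interaction type (C+M vs C) with between-network
(HmN/HtN) and across-species (HmS/HtS) dispersal heterogeneity.  The full
rate grid is `{0} ∪ {e^(−4+0.25k)}`, 30 values up to `e³`.  The
zero-dispersal baseline is integrated once per community and interaction
type and reused across grid points.  Per-cell failures are flagged in the
output table, never silently dropped.  `run_cell` accepts a metric
selection so sweeps that only need a subset (e.g. similarity and spectra)
skip the costlier structure metrics.

The bundled reproduction script (`scripts/acceptance.py`) and the
sweep-based tests use a reduced design chosen as a representative scale:
11 grid values spanning `e⁻⁴`–`e³`, 3 replicate communities, all 8
scenarios at the standard community size (M=30, N=20, n=10, C=0.2).

## What the generator does and does not emulate

The synthetic communities realise the stated parameter laws exactly, so
passing tests demonstrate the dynamical and spectral mechanisms —
negative feedback, spectral splitting, mutualism's abundance and
stability effects — under those laws.  They do not demonstrate anything
about empirical plant–pollinator networks: real networks have broad
degree distributions (here: uniform random incidence), correlated
interaction strengths, environmental noise, and landscape structure
(here: fully connected, spatially implicit patches).  Gini values here
(~0.05–0.15) are far below empirical abundance inequality, because
sampled equilibria concentrate near carrying capacity.

## Known limitations

- The spatial Morisita–Horn floor across all sweep cells is ≈0.93, not
  higher: independent per-network parameter draws bound weak-dispersal
  similarity, and the flat-Dirichlet partition bounds the
  heterogeneous-between cells at strong dispersal.
- Mutualism's effect on Gini unevenness is a near-tie (C+M very slightly
  more uneven at these parameter scales): positive benefit heterogeneity
  adds abundance spread of the same order as the mean lift it provides.
- Equilibrium is asserted at `t = 50` with a residual check rather than
  proven; multistability, limit cycles and extinction events are not
  detected beyond the residual and non-negativity flags.
- The modularity search is exact only where exhaustive enumeration is
  feasible; on large matrices it is a stochastic maximiser and the
  returned Q is a lower bound on the optimum.
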