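import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanet import (
    MetaState,
    bipartite_modularity,
    gini,
    gini_local_mean,
    meta_relative_abundance,
    morisita_horn_spatial,
    morisita_horn_temporal,
    total_abundance,
    weighted_matrix,
    wnodf,
)
from metanet._lpawb import barber_modularity


def set_partitions(items):
    """All partitions of a list into non-empty unlabeled blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_q(w):
    """Exhaustive Barber-Q maximisation over all node partitions."""
    nr, nc = w.shape
    nodes = list(range(nr + nc))
    best = -np.inf
    for part in set_partitions(nodes):
        rl = np.empty(nr, dtype=int)
        cl = np.empty(nc, dtype=int)
        for lab, block in enumerate(part):
            for node in block:
                if node < nr:
                    rl[node] = lab
                else:
                    cl[node - nr] = lab
        best = max(best, barber_modularity(w, rl, cl))
    return max(best, 0.0)


class TestTotalAbundance:
    def test_zero_state(self):
        assert total_abundance(MetaState(P=np.zeros((1, 2)), A=np.zeros((1, 2)))) == 0

    def test_unit_abundances_count_species_networks(self):
        st_ = MetaState(P=np.ones((1, 2)), A=np.ones((1, 2)))
        assert total_abundance(st_) == 4.0

    def test_network_permutation_invariance(self, rng):
        P, A = rng.uniform(0, 1, (3, 4)), rng.uniform(0, 1, (2, 4))
        s1 = MetaState(P=P, A=A)
        s2 = MetaState(P=P[:, ::-1], A=A[:, ::-1])
        assert total_abundance(s1) == pytest.approx(total_abundance(s2))


class TestGini:
    def test_perfect_evenness_is_zero(self):
        assert gini(np.full(50, 1.0)) == pytest.approx(0.0, abs=1e-15)

    def test_small_example(self):
        # mean-absolute-difference oracle: sum|xi-xj| / (2 S^2 mean) = 8/36
        assert gini(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0 / 9.0)

    @given(seed=st.integers(0, 2**16), S=st.integers(2, 30))
    @settings(deadline=None, max_examples=60)
    def test_matches_mean_absolute_difference_oracle(self, seed, S):
        x = np.random.default_rng(seed).uniform(0.01, 5.0, S)
        mad = np.abs(x[:, None] - x[None, :]).sum() / (2 * S**2 * x.mean())
        assert gini(x) == pytest.approx(mad, abs=1e-12)
        assert 0.0 <= gini(x) <= 1.0 - 1.0 / S

    @given(c=st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, c):
        x = np.array([0.2, 1.0, 3.7, 0.9])
        assert gini(c * x) == pytest.approx(gini(x), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini(np.zeros(4))

    def test_local_mean_averages_per_network_values(self, rng):
        s = MetaState(P=rng.uniform(0.1, 2, (3, 2)), A=rng.uniform(0.1, 2, (2, 2)))
        X = s.stacked()
        expect = np.mean([gini(X[:, 0]), gini(X[:, 1])])
        assert gini_local_mean(s) == pytest.approx(expect)


class TestMorisitaHorn:
    def test_identical_networks_give_one(self):
        col = np.array([[0.4], [0.3], [0.3]])
        s = MetaState(P=np.tile(col[:2], 3), A=np.tile(col[2:], 3))
        assert morisita_horn_spatial(s) == pytest.approx(1.0)

    def test_disjoint_networks_give_zero(self):
        s = MetaState(
            P=np.array([[1.0, 0.0], [2.0, 0.0]]),
            A=np.array([[0.0, 1.0], [0.0, 3.0]]),
        )
        assert morisita_horn_spatial(s) == pytest.approx(0.0)

    def test_hand_example_two_networks(self):
        # p1 = (0.5, 0.5), p2 = (1, 0) -> 2*0.5 / (0.25+0.25+1) = 2/3
        s = MetaState(P=np.array([[0.5, 1.0]]), A=np.array([[0.5, 0.0]]))
        assert morisita_horn_spatial(s) == pytest.approx(2.0 / 3.0)

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, max_examples=40)
    def test_spatial_bounds_and_permutation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        P, A = rng.uniform(0, 2, (3, 4)) + 0.01, rng.uniform(0, 2, (2, 4)) + 0.01
        c = morisita_horn_spatial(MetaState(P=P, A=A))
        perm = rng.permutation(4)
        c2 = morisita_horn_spatial(MetaState(P=P[:, perm], A=A[:, perm]))
        assert 0.0 <= c <= 1.0 + 1e-12
        assert c == pytest.approx(c2)

    def test_zero_total_network_rejected(self):
        s = MetaState(P=np.array([[1.0, 0.0]]), A=np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError):
            morisita_horn_spatial(s)

    def test_temporal_identity(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        assert morisita_horn_temporal(q, q) == pytest.approx(1.0)

    def test_temporal_disjoint_supports(self):
        assert morisita_horn_temporal(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(0.0)

    def test_temporal_hand_example(self):
        assert morisita_horn_temporal(
            np.array([0.5, 0.5]), np.array([1.0, 0.0])
        ) == pytest.approx(2.0 / 3.0)

    def test_temporal_symmetry(self, rng):
        qa = rng.dirichlet(np.ones(6))
        qb = rng.dirichlet(np.ones(6))
        assert morisita_horn_temporal(qa, qb) == pytest.approx(
            morisita_horn_temporal(qb, qa)
        )

    def test_unnormalised_inputs_rejected(self):
        with pytest.raises(ValueError):
            morisita_horn_temporal(np.array([0.5, 0.4]), np.array([0.5, 0.5]))

    def test_meta_relative_abundance_sums_to_one(self, rng):
        s = MetaState(P=rng.uniform(0, 1, (3, 2)), A=rng.uniform(0, 1, (2, 2)))
        q = meta_relative_abundance(s)
        assert q.sum() == pytest.approx(1.0)
        assert q.shape == (5,)


class TestWeightedMatrix:
    def test_empty_topology_gives_zero_weights(self):
        s = MetaState(P=np.ones((2, 2)), A=np.ones((2, 2)))
        w = weighted_matrix(np.zeros((2, 2), dtype=int), s, "meta")
        assert not w.w.any()

    def test_single_link_product(self):
        s = MetaState(P=np.array([[2.0]]), A=np.array([[3.0]]))
        w = weighted_matrix(np.array([[1]]), s, 0)
        assert w.w[0, 0] == pytest.approx(6.0)

    def test_meta_is_sum_of_locals(self, rng):
        a = (rng.uniform(size=(3, 2)) < 0.6).astype(int)
        s = MetaState(P=rng.uniform(0, 2, (3, 4)), A=rng.uniform(0, 2, (2, 4)))
        meta = weighted_matrix(a, s, "meta").w
        locals_ = sum(weighted_matrix(a, s, k).w for k in range(4))
        np.testing.assert_allclose(meta, locals_, atol=1e-12)


class TestWnodf:
    def test_perfectly_nested_two_by_two(self):
        assert wnodf(np.array([[5.0, 3.0], [2.0, 0.0]])) == pytest.approx(100.0)

    def test_identical_lines_score_zero(self):
        assert wnodf(np.array([[2.0, 2.0], [2.0, 2.0]])) == pytest.approx(0.0)

    @given(c=st.floats(1.001, 50.0))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_positive_scaling(self, c):
        w = np.array([[4.0, 1.0, 0.0], [3.0, 2.0, 1.0], [1.0, 0.0, 0.0]])
        assert wnodf(c * w) == pytest.approx(wnodf(w))

    def test_transpose_symmetry(self, rng):
        w = rng.uniform(0, 1, (4, 6)) * (rng.uniform(size=(4, 6)) < 0.5)
        assert wnodf(w) == pytest.approx(wnodf(w.T))

    def test_row_order_invariance(self, rng):
        w = rng.uniform(0, 2, (5, 4)) * (rng.uniform(size=(5, 4)) < 0.7)
        assert wnodf(w[rng.permutation(5)]) == pytest.approx(wnodf(w))

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            wnodf(np.array([[1.0, 2.0]]))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_vegan_weighted_nodf(self, rng, tmp_path):
        # independent oracle: vegan::nestednodf(..., weighted=TRUE, order=TRUE)
        mats = [
            rng.integers(0, 6, (5, 4)).astype(float),
            rng.uniform(0, 1, (6, 6)) * (rng.uniform(size=(6, 6)) < 0.5),
            np.array([[4.0, 1.0, 0.0], [3.0, 2.0, 1.0], [1.0, 0.0, 0.0]]),
        ]
        for idx, m in enumerate(mats):
            csv = tmp_path / f"m{idx}.csv"
            np.savetxt(csv, m, delimiter=",")
            script = textwrap.dedent(
                f"""
                suppressMessages(library(vegan))
                m <- as.matrix(read.csv("{csv}", header=FALSE))
                s <- nestednodf(m, weighted=TRUE, order=TRUE)$statistic
                cat(sprintf("%.10f", s[["NODF"]]))
                """
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, check=True
            )
            assert wnodf(m) == pytest.approx(float(out.stdout), abs=1e-6)


class TestModularity:
    def test_single_module_partition_has_zero_q(self, rng):
        w = rng.uniform(0, 1, (3, 3))
        assert barber_modularity(w, np.zeros(3, int), np.zeros(3, int)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_perfect_two_module_matrix(self, rng):
        w = np.array([[1.0, 0.0], [0.0, 1.0]])
        q, (rl, cl) = bipartite_modularity(w, rng)
        assert q == pytest.approx(0.5)
        assert rl[0] == cl[0] and rl[1] == cl[1] and rl[0] != rl[1]

    def test_never_below_zero(self, rng):
        w = np.ones((3, 3))  # unstructured: best is the trivial partition
        q, _ = bipartite_modularity(w, rng)
        assert q >= 0.0

    def test_deterministic_given_seed(self):
        w = np.array([[3.0, 1.0, 0.0], [0.0, 2.0, 1.0], [1.0, 0.0, 4.0]])
        q1, _ = bipartite_modularity(w, np.random.default_rng(5))
        q2, _ = bipartite_modularity(w, np.random.default_rng(5))
        assert q1 == q2

    def test_zero_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            bipartite_modularity(np.zeros((2, 2)), rng)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        shape = [(2, 2), (2, 3), (3, 3), (2, 4), (3, 2), (2, 2)][seed]
        w = rng.uniform(0, 1, shape) * (rng.uniform(size=shape) < 0.7)
        if w.sum() == 0:
            w[0, 0] = 1.0
        q, _ = bipartite_modularity(w, np.random.default_rng(seed + 100))
        assert q == pytest.approx(brute_force_q(w), abs=1e-10)
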