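import numpy as np
import pytest
import scipy.linalg

from randsig import (
    ScoreVector,
    WeightedNetwork,
    build_laplacian,
    call_significant_genes,
    diffuse,
    diffusion_kernel,
    occurrence_scores,
    permutation_scores,
)


def random_network(n, p, seed, wlo=0.2, whi=1.0):
    rng = np.random.default_rng(seed)
    edges = []
    names = [f"g{i}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j], float(rng.uniform(wlo, whi))))
    if not edges:
        edges = [(names[0], names[1], 0.5)]
    return names, WeightedNetwork.from_edges(edges)


class TestOccurrenceScores:
    def test_counts_memberships(self):
        sigs = [["a", "b"]] * 20 + [["b", "c"]] * 5
        sv = occurrence_scores(sigs, ["a", "b", "c", "d"])
        np.testing.assert_array_equal(sv.values, [20, 25, 5, 0])

    def test_total_mass_equals_sum_of_sizes(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        sigs = [list(rng.choice(genes, size=5, replace=False)) for _ in range(40)]
        sv = occurrence_scores(sigs, genes)
        assert sv.values.sum() == sum(len(s) for s in sigs)


class TestLaplacian:
    def test_two_node_hand_example(self):
        net = WeightedNetwork.from_edges([("a", "b", 2.0)])
        H = build_laplacian(net, ["a", "b"]).toarray()
        np.testing.assert_array_equal(H, [[2, -2], [-2, 2]])

    def test_isolated_gene_has_zero_row_and_column(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0)])
        H = build_laplacian(net, ["a", "b", "iso"]).toarray()
        np.testing.assert_array_equal(H[2], 0)
        np.testing.assert_array_equal(H[:, 2], 0)

    def test_rows_sum_to_zero(self):
        names, net = random_network(25, 0.2, seed=1)
        H = build_laplacian(net, names)
        np.testing.assert_allclose(np.asarray(H.sum(axis=1)).ravel(), 0, atol=1e-12)


class TestKernel:
    def test_beta_zero_is_identity(self):
        names, net = random_network(10, 0.3, seed=2)
        op = diffusion_kernel(build_laplacian(net, names), 0.0, gene_ids=names)
        np.testing.assert_allclose(op.materialize(), np.eye(10), atol=1e-12)

    def test_two_node_closed_form(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0)])
        op = diffusion_kernel(build_laplacian(net, ["a", "b"]), 0.3, gene_ids=["a", "b"])
        d, o = (1 + np.exp(-0.6)) / 2, (1 - np.exp(-0.6)) / 2
        np.testing.assert_allclose(op.materialize(), [[d, o], [o, d]], atol=1e-10)

    @pytest.mark.parametrize("n,seed", [(20, 3), (50, 4), (120, 5)])
    def test_matches_dense_expm_oracle(self, n, seed):
        names, net = random_network(n, 4.0 / n, seed=seed)
        H = build_laplacian(net, names).toarray()
        op = diffusion_kernel(H, 0.3, gene_ids=names)
        ref = scipy.linalg.expm(-0.3 * H)
        np.testing.assert_allclose(op.materialize(), ref, atol=1e-8)

    def test_symmetric_nonnegative_unit_column_sums(self):
        names, net = random_network(60, 0.1, seed=6)
        K = diffusion_kernel(build_laplacian(net, names), 0.5, gene_ids=names).materialize()
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert K.min() >= 0.0
        np.testing.assert_allclose(K.sum(axis=0), 1.0, atol=1e-8)

    def test_action_path_matches_dense_path(self):
        names, net = random_network(40, 0.15, seed=7)
        H = build_laplacian(net, names)
        dense = diffusion_kernel(H, 0.3, gene_ids=names)
        action = diffusion_kernel(H, 0.3, gene_ids=names, dense_limit=10)
        rng = np.random.default_rng(0)
        v = rng.uniform(size=40)
        np.testing.assert_allclose(action.apply(v), dense.apply(v), atol=1e-8)

    def test_negative_beta_rejected(self):
        names, net = random_network(5, 0.5, seed=8)
        with pytest.raises(ValueError, match="beta"):
            diffusion_kernel(build_laplacian(net, names), -0.1, gene_ids=names)


class TestDiffuse:
    def test_isolated_gene_keeps_score(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0)])
        names = ["a", "b", "iso"]
        op = diffusion_kernel(build_laplacian(net, names), 0.7, gene_ids=names)
        out = diffuse(op, ScoreVector(names, [0.0, 0.0, 7.0]))
        assert out.values[2] == pytest.approx(7.0, abs=1e-12)

    def test_two_node_example(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0)])
        op = diffusion_kernel(build_laplacian(net, ["a", "b"]), 0.3, gene_ids=["a", "b"])
        out = diffuse(op, ScoreVector(["a", "b"], [1.0, 0.0]))
        np.testing.assert_allclose(
            out.values, [(1 + np.exp(-0.6)) / 2, (1 - np.exp(-0.6)) / 2], atol=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mass_conservation(self, seed):
        names, net = random_network(35, 0.12, seed=seed)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        rng = np.random.default_rng(seed)
        sv = ScoreVector(names, rng.integers(0, 30, size=35).astype(float))
        out = diffuse(op, sv)
        assert out.values.sum() == pytest.approx(sv.values.sum(), abs=1e-8)

    def test_beta_to_zero_limit_recovers_raw_scores(self):
        names, net = random_network(30, 0.15, seed=9)
        op = diffusion_kernel(build_laplacian(net, names), 1e-8, gene_ids=names)
        rng = np.random.default_rng(1)
        sv = ScoreVector(names, rng.integers(0, 10, size=30).astype(float))
        out = diffuse(op, sv)
        assert np.max(np.abs(out.values - sv.values)) <= 1e-6

    def test_ordering_mismatch_rejected(self):
        names, net = random_network(5, 0.5, seed=3)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        with pytest.raises(ValueError, match="ordering"):
            diffuse(op, ScoreVector(names[::-1], np.ones(5)))

    def test_star_graph_leaves_get_equal_positive_mass(self):
        leaves = [f"leaf{i}" for i in range(6)]
        net = WeightedNetwork.from_edges([("hub", l, 0.8) for l in leaves])
        names = ["hub"] + leaves
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        out = diffuse(op, ScoreVector(names, [10.0] + [0.0] * 6))
        leaf_vals = out.values[1:]
        assert np.all(leaf_vals > 0)
        np.testing.assert_allclose(leaf_vals, leaf_vals[0])


class TestPermutationScores:
    def test_exhaustive_identity_kernel_three_genes(self):
        names = ["a", "b", "c"]
        net = WeightedNetwork(__import__("networkx").Graph())
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        sv = ScoreVector(names, [10.0, 5.0, 1.0])
        ps = permutation_scores(op, sv, n_perm=1, seed=0, exhaustive=True)
        np.testing.assert_allclose(ps, [2 / 6, 4 / 6, 6 / 6])

    def test_constant_scores_give_permutation_score_one(self):
        names, net = random_network(8, 0.3, seed=4)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        ps = permutation_scores(op, ScoreVector(names, np.full(8, 3.0)), 50, seed=1)
        np.testing.assert_allclose(ps, 1.0)

    def test_monte_carlo_converges_to_exhaustive_six_genes(self):
        names, net = random_network(6, 0.5, seed=5)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        sv = ScoreVector(names, np.array([12.0, 7.0, 3.0, 1.0, 0.0, 0.0]))
        exact = permutation_scores(op, sv, 1, seed=0, exhaustive=True)
        n_mc = 10000
        mc = permutation_scores(op, sv, n_mc, seed=2)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert np.all(np.abs(mc - exact) <= 3 * se + 1e-12)

    def test_deterministic_per_seed(self):
        names, net = random_network(10, 0.3, seed=6)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        sv = ScoreVector(names, np.arange(10.0))
        a = permutation_scores(op, sv, 100, seed=7)
        b = permutation_scores(op, sv, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_null_modes_agree_at_beta_zero(self):
        names, net = random_network(10, 0.3, seed=8)
        op = diffusion_kernel(build_laplacian(net, names), 0.0, gene_ids=names)
        sv = ScoreVector(names, np.arange(10.0))
        a = permutation_scores(op, sv, 200, seed=9, null_mode="as-printed")
        b = permutation_scores(op, sv, 200, seed=9, null_mode="raw-scores")
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs_rejected(self):
        names, net = random_network(5, 0.5, seed=9)
        op = diffusion_kernel(build_laplacian(net, names), 0.3, gene_ids=names)
        sv = ScoreVector(names, np.ones(5))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_scores(op, sv, 0, seed=0)
        with pytest.raises(ValueError, match="null_mode"):
            permutation_scores(op, sv, 10, seed=0, null_mode="bogus")


class TestCallSignificantGenes:
    def test_filter_and_rank(self):
        calls = call_significant_genes(
            ["g1", "g2", "g3"], np.array([5.0, 4, 3]),
            np.array([5.5, 4.4, 3.3]), np.array([0.001, 0.2, 0.04]),
        )
        assert [c.gene_id for c in calls] == ["g1", "g3"]
        assert calls[0].rank == 1 and calls[1].rank == 2

    def test_all_above_alpha_empty(self):
        calls = call_significant_genes(
            ["a", "b"], np.zeros(2), np.zeros(2), np.array([0.05, 0.9])
        )
        assert calls == []  # 0.05 itself is excluded (strict <)

    def test_tie_broken_by_diffusion_score(self):
        calls = call_significant_genes(
            ["a", "b"], np.array([1.0, 2.0]),
            np.array([4.0, 9.0]), np.array([0.01, 0.01]),
        )
        assert [c.gene_id for c in calls] == ["b", "a"]

    def test_full_tie_broken_by_gene_id(self):
        calls = call_significant_genes(
            ["z", "a"], np.ones(2), np.ones(2), np.array([0.01, 0.01])
        )
        assert [c.gene_id for c in calls] == ["a", "z"]
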