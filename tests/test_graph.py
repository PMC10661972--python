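import numpy as np
import pytest

from reglink import (
    PriorNetwork,
    ReglinkError,
    build_normalized_adjacency,
    density_matched_test_negatives,
    make_split,
    sample_hard_negatives,
    split_positives,
)
from reglink.graph import _split_counts


def _random_net(rng, n_genes=10, n_tfs=4, p=0.3):
    genes = tuple(f"g{i}" for i in range(n_genes))
    tfs = genes[:n_tfs]
    edges = frozenset(
        (s, t) for s in tfs for t in genes if s != t and rng.random() < p
    )
    return PriorNetwork(genes, edges, frozenset(tfs))


class TestNormalizedAdjacency:
    def test_single_isolated_node(self):
        net = PriorNetwork(("A", "B"), frozenset({("A", "B")}), frozenset({"A"}))
        a = build_normalized_adjacency(net, ["A"], frozenset())
        np.testing.assert_array_equal(a.matrix, [[1.0]])

    def test_two_nodes_one_edge_all_half(self):
        net = PriorNetwork(("A", "B"), frozenset({("A", "B")}), frozenset({"A"}))
        a = build_normalized_adjacency(net, ["A", "B"], net.edges)
        np.testing.assert_allclose(a.matrix, np.full((2, 2), 0.5))

    def test_three_node_path_entry(self):
        # path A-B-C with self-loops: degrees 2,3,2; entry (A,B) = 1/sqrt(6)
        net = PriorNetwork(
            ("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}), frozenset({"A", "B"})
        )
        a = build_normalized_adjacency(net, ["A", "B", "C"], net.edges)
        assert a.matrix[0, 1] == pytest.approx(1 / np.sqrt(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_elementwise_formula_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_net(rng)
        a = build_normalized_adjacency(net, net.genes, net.edges)
        # brute-force oracle: A_ij / sqrt(d_i d_j) on the self-looped
        # symmetrised binary adjacency
        n = len(net.genes)
        idx = {g: i for i, g in enumerate(net.genes)}
        raw = np.eye(n)
        for s, t in net.edges:
            raw[idx[s], idx[t]] = raw[idx[t], idx[s]] = 1.0
        d = raw.sum(1)
        oracle = np.array(
            [[raw[i, j] / np.sqrt(d[i] * d[j]) for j in range(n)] for i in range(n)]
        )
        np.testing.assert_allclose(a.matrix, oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_spectral_radius_at_most_one(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = _random_net(rng, n_genes=15, n_tfs=6)
        a = build_normalized_adjacency(net, net.genes, net.edges)
        eig = np.linalg.eigvalsh(a.matrix)
        assert eig.max() <= 1.0 + 1e-10


class TestSplitPositives:
    @pytest.mark.parametrize("n,expected", [(10, (6, 2, 2)), (5, (3, 1, 1)),
                                            (7, (5, 1, 1)), (8, (5, 2, 1))])
    def test_counts(self, n, expected):
        assert _split_counts(n) == expected

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        net = _random_net(rng, n_genes=20, n_tfs=8, p=0.4)
        split = split_positives(net, seed=3)
        union = split.train_pos | split.val_pos | split.test_pos
        assert union == net.edges
        assert len(split.train_pos) + len(split.val_pos) + len(split.test_pos) == len(net.edges)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        net = _random_net(rng, n_genes=20, n_tfs=8, p=0.4)
        assert split_positives(net, 9).train_pos == split_positives(net, 9).train_pos

    def test_fewer_than_five_errors(self):
        net = PriorNetwork(("A", "B", "C"), frozenset({("A", "B")}), frozenset({"A"}))
        with pytest.raises(ReglinkError, match="at least 5"):
            split_positives(net, 0)


class TestHardNegatives:
    def test_single_candidate_enumerated(self):
        net = PriorNetwork(("A", "B", "C"), frozenset({("A", "B")}), frozenset({"A"}))
        neg = sample_hard_negatives({("A", "B")}, net.edges, net, ratio=1.0, seed=0)
        assert neg == {("A", "C")}

    def test_never_returns_true_edges(self):
        rng = np.random.default_rng(2)
        net = _random_net(rng, n_genes=12, n_tfs=5, p=0.4)
        neg = sample_hard_negatives(net.edges, net.edges, net, ratio=2.0, seed=1)
        assert not (neg & net.edges)

    def test_sources_share_positive_tf_when_pool_allows(self):
        rng = np.random.default_rng(3)
        net = _random_net(rng, n_genes=12, n_tfs=5, p=0.3)
        pos = set(list(net.edges)[:5])
        neg = sample_hard_negatives(pos, net.edges, net, ratio=1.0, seed=4)
        pos_sources = {s for s, _ in pos}
        assert all(s in pos_sources for s, _ in neg)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        net = _random_net(rng)
        a = sample_hard_negatives(net.edges, net.edges, net, 1.0, seed=5)
        b = sample_hard_negatives(net.edges, net.edges, net, 1.0, seed=5)
        assert a == b

    def test_exhausted_pool_samples_up_to_size(self, caplog):
        # TF A has one non-edge target only; requesting 3 negatives per
        # positive exhausts the pool
        net = PriorNetwork(("A", "B", "C"), frozenset({("A", "B")}), frozenset({"A"}))
        neg = sample_hard_negatives({("A", "B")}, net.edges, net, ratio=3.0, seed=0)
        assert neg == {("A", "C")}


class TestDensityMatchedNegatives:
    @pytest.mark.parametrize("rho,n_pos,expected", [(0.5, 10, 10), (0.2, 10, 40)])
    def test_counts(self, rho, n_pos, expected):
        # build a network with exact density rho over a large candidate grid
        n_genes, n_tfs = 41, 10
        genes = tuple(f"g{i}" for i in range(n_genes))
        tfs = genes[:n_tfs]
        possible = [(s, t) for s in tfs for t in genes if s != t]
        k = int(round(rho * len(possible)))
        net = PriorNetwork(genes, frozenset(possible[:k]), frozenset(tfs))
        assert net.density == pytest.approx(rho)
        test_pos = set(possible[:n_pos])
        neg = density_matched_test_negatives(test_pos, net, seed=0)
        assert len(neg) == expected

    def test_sources_are_tfs_and_disjoint_from_positives(self):
        rng = np.random.default_rng(5)
        net = _random_net(rng, n_genes=15, n_tfs=5, p=0.3)
        pos = set(list(net.edges)[:4])
        neg = density_matched_test_negatives(pos, net, seed=1)
        assert all(s in net.tf_set for s, _ in neg)
        assert not (neg & net.edges)


class TestMakeSplit:
    def test_full_split_invariants(self):
        rng = np.random.default_rng(6)
        net = _random_net(rng, n_genes=30, n_tfs=10, p=0.3)
        split = make_split(net, seed=2)
        all_pos = split.all_positives
        assert all_pos == net.edges
        negs = [split.train_neg, split.val_neg, split.test_neg]
        for i, a in enumerate(negs):
            assert not (a & all_pos)
            for b in negs[i + 1:]:
                assert not (a & b)
        assert all(s in net.tf_set for group in negs for s, _ in group)

    def test_reproducible(self):
        rng = np.random.default_rng(7)
        net = _random_net(rng, n_genes=30, n_tfs=10, p=0.3)
        a, b = make_split(net, seed=3), make_split(net, seed=3)
        assert (a.train_pos, a.train_neg, a.test_neg) == (b.train_pos, b.train_neg, b.test_neg)
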