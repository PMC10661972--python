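import numpy as np
import pytest

from reglink import (
    ExpressionMatrix,
    GCNModel,
    PriorNetwork,
    ReglinkError,
    ScoreMatrix,
    TrainConfig,
    build_normalized_adjacency,
    compute_loss,
    make_split,
    run_pipeline,
    train,
)
from reglink.model import loss_and_grads, propagation_matrix


@pytest.fixture
def three_node_setup():
    """3 genes, 4 cells, one edge: the smallest trainable problem."""
    rng = np.random.default_rng(0)
    genes = ("A", "B", "C")
    x = ExpressionMatrix(genes, ("c1", "c2", "c3", "c4"), np.abs(rng.normal(size=(3, 4))))
    net = PriorNetwork(genes, frozenset({("A", "B")}), frozenset({"A"}))
    a = build_normalized_adjacency(net, genes, net.edges)
    return x, net, a


class TestComputeLoss:
    def _score(self, mapping, genes=("A", "B", "C")):
        n = len(genes)
        m = np.zeros((n, n))
        idx = {g: i for i, g in enumerate(genes)}
        for (s, t), v in mapping.items():
            m[idx[s], idx[t]] = m[idx[t], idx[s]] = v
        return ScoreMatrix(m, tuple(genes))

    def test_exact_predictions_give_zero(self):
        r = self._score({("A", "B"): 1.0, ("A", "C"): 0.0})
        model = GCNModel.init_glorot((4, 2), seed=0)
        samples = [("A", "B", 1), ("A", "C", 0)]
        assert compute_loss(r, samples, model, weight_decay=0.0) == 0.0

    def test_single_missed_positive(self):
        r = self._score({})
        model = GCNModel.init_glorot((4, 2), seed=0)
        assert compute_loss(r, [("A", "B", 1)], model, 0.0) == 1.0

    def test_half_scores_give_quarter(self):
        r = self._score({("A", "B"): 0.5, ("A", "C"): 0.5})
        model = GCNModel.init_glorot((4, 2), seed=0)
        samples = [("A", "B", 1), ("A", "C", 0)]
        assert compute_loss(r, samples, model, 0.0) == pytest.approx(0.25)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        r = self._score({("A", "B"): 0.7, ("A", "C"): 0.2, ("B", "C"): 0.9})
        model = GCNModel.init_glorot((4, 2), seed=0)
        samples = [("A", "B", 1), ("A", "C", 0), ("B", "C", 1)]
        shuffled = [samples[i] for i in rng.permutation(3)]
        assert compute_loss(r, samples, model, 1e-3) == pytest.approx(
            compute_loss(r, shuffled, model, 1e-3)
        )

    def test_weight_decay_adds_frobenius_term(self):
        r = self._score({("A", "B"): 1.0})
        model = GCNModel.init_glorot((4, 2), seed=0)
        frob = sum(float(np.sum(w * w)) for w in model.weights)
        base = compute_loss(r, [("A", "B", 1)], model, 0.0)
        assert compute_loss(r, [("A", "B", 1)], model, 0.1) == pytest.approx(base + 0.1 * frob)

    def test_empty_samples_error(self):
        r = self._score({})
        model = GCNModel.init_glorot((4, 2), seed=0)
        with pytest.raises(ReglinkError):
            compute_loss(r, [], model, 0.0)


class TestGradients:
    def test_finite_difference_agreement(self, three_node_setup):
        x, net, a = three_node_setup
        model = GCNModel.init_glorot((4, 3, 2), lambda_mix=0.6, seed=1)
        p = propagation_matrix(a, model.lambda_mix)
        ii = np.array([0, 0])
        jj = np.array([1, 2])
        labels = np.array([1.0, 0.0])
        wd = 0.01
        _, grads_w, grads_b = loss_and_grads(x.values, p, model, ii, jj, labels, wd)
        eps = 1e-6
        for layer in range(model.n_layers):
            for arr, grad in ((model.weights[layer], grads_w[layer]),
                              (model.biases[layer], grads_b[layer])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    k = it.multi_index
                    orig = arr[k]
                    arr[k] = orig + eps
                    lp, _, _ = loss_and_grads(x.values, p, model, ii, jj, labels, wd)
                    arr[k] = orig - eps
                    lm, _, _ = loss_and_grads(x.values, p, model, ii, jj, labels, wd)
                    arr[k] = orig
                    numeric = (lp - lm) / (2 * eps)
                    denom = max(abs(numeric), abs(grad[k]), 1e-8)
                    assert abs(numeric - grad[k]) / denom < 1e-4


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, smoke_data):
        x, net = smoke_data
        from reglink import preprocess_pipeline
        xp, _ = preprocess_pipeline(x, net.tf_set)
        net_r = net.restrict(xp.gene_ids)
        split = make_split(net_r, seed=0)
        cfg = TrainConfig(epochs=5, learning_rate=0.0, seed=0)
        model, _ = train(xp, net_r, split, cfg)
        reference = GCNModel.init_glorot(
            (xp.n_cells, *cfg.hidden_dims), cfg.lambda_mix,
            seed=int(np.random.SeedSequence(0).generate_state(1)[0] % (2**31)),
        )
        for a, b in zip(model.weights, reference.weights):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_history(self, smoke_data):
        x, net = smoke_data
        from reglink import preprocess_pipeline
        xp, _ = preprocess_pipeline(x, net.tf_set)
        net_r = net.restrict(xp.gene_ids)
        split = make_split(net_r, seed=1)
        cfg = TrainConfig(epochs=10, seed=1)
        _, h1 = train(xp, net_r, split, cfg)
        _, h2 = train(xp, net_r, split, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_auroc == h2.val_auroc

    def test_loss_decreases_on_smoke_fixture(self, smoke_data):
        x, net = smoke_data
        _, history, *_ = run_pipeline(x, net, TrainConfig(seed=0))
        assert history.train_loss[-1] < 0.9 * history.train_loss[0]

    def test_best_epoch_maximises_validation_auroc(self, smoke_data):
        x, net = smoke_data
        _, history, *_ = run_pipeline(x, net, TrainConfig(epochs=30, seed=2))
        assert history.val_auroc[history.best_epoch] == max(history.val_auroc)
        assert len(history.train_loss) == len(history.val_auroc) == 30

    def test_weight_decay_shrinks_weights_with_zero_labels(self, three_node_setup):
        # all-negative labels plus Frobenius penalty: trained weight norms
        # shrink relative to their initial values
        x, net, a = three_node_setup
        from reglink.graph import EdgeSplit
        split = EdgeSplit(
            train_pos=frozenset(), val_pos=frozenset(), test_pos=frozenset(),
            train_neg=frozenset({("A", "B"), ("A", "C")}),
        )
        cfg = TrainConfig(epochs=50, weight_decay=0.05, seed=3, hidden_dims=(4, 2))
        model, history = train(x, net, split, cfg, a_norm=a)
        init = GCNModel.init_glorot(
            (4, 4, 2), cfg.lambda_mix,
            seed=int(np.random.SeedSequence(3).generate_state(1)[0] % (2**31)),
        )
        trained_norm = sum(np.sum(w**2) for w in model.weights)
        init_norm = sum(np.sum(w**2) for w in init.weights)
        assert trained_norm < init_norm


class TestRunPipeline:
    def test_end_to_end_smoke(self, smoke_data, tmp_path):
        from reglink import run_experiment
        from reglink.synthetic import make_fixture
        _, _, paths = make_fixture("smoke", tmp_path / "inputs")
        ranked, metrics = run_experiment(
            paths["expression"], paths["network"], paths["tfs"],
            TrainConfig(epochs=20, seed=0), tmp_path / "run",
        )
        assert ranked.exists()
        assert (tmp_path / "run" / "metrics.json").exists()
        from reglink.graph import _split_counts
        sizes = metrics["split_sizes"]
        n = sizes["train_pos"] + sizes["val_pos"] + sizes["test_pos"]
        assert (sizes["train_pos"], sizes["val_pos"], sizes["test_pos"]) == _split_counts(n)
        assert 0.0 <= metrics["test"]["auroc"] <= 1.0

    def test_different_seeds_beat_chance_on_strong_signal(self, strong_signal_data):
        x, net = strong_signal_data
        aurocs = [
            run_pipeline(x, net, TrainConfig(seed=s))[4].auroc for s in (0, 1)
        ]
        assert all(a > 0.5 for a in aurocs)
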