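import numpy as np
import pytest

from pgxgraph._nn import sigmoid
from pgxgraph.kg import graph_operator
from pgxgraph.model import (
    DenseUsageClassifier,
    GCNUsageClassifier,
    LogisticUsageClassifier,
    aggregate_patient_embedding,
    bce_loss,
    build_model,
    gcn_forward,
    split_sizes,
    stratified_split,
    train,
)
from pgxgraph.synthdata import SimConfig, simulate

from conftest import random_graph


def dense_gcn_oracle(S, weights, act):
    """Step-by-step dense reference: H^{l+1} = act(S H^l W^l), H^0 = I."""
    H = np.eye(S.shape[0])
    for W in weights:
        H = act(S @ (H @ W))
    return H


class TestGCNForward:
    def test_identity_weights_identity_activation_gives_S(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, n_nodes=6)
        S = graph_operator(g)
        H = gcn_forward(S, [np.eye(6)], activation="identity")
        np.testing.assert_allclose(H, S.toarray(), atol=1e-12)

    def test_edgeless_graph_reduces_to_weight_product(self):
        S = np.eye(4)
        rng = np.random.default_rng(1)
        W = [rng.normal(size=(4, 3)), rng.normal(size=(3, 2))]
        H = gcn_forward(S, W, activation="identity")
        np.testing.assert_allclose(H, W[0] @ W[1], atol=1e-12)

    def test_identity_weights_L_layers_is_S_power(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n_nodes=7)
        S = graph_operator(g).toarray()
        H = gcn_forward(S, [np.eye(7)] * 3, activation="identity")
        np.testing.assert_allclose(H, np.linalg.matrix_power(S, 3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, n_nodes=int(rng.integers(3, 51)), p_edge=0.2)
        S = graph_operator(g)
        n = g.n_nodes
        dims = [n, int(rng.integers(2, 9)), int(rng.integers(2, 9))]
        W = [rng.normal(size=(a, b)) for a, b in zip(dims[:-1], dims[1:])]
        H = gcn_forward(S, W, activation="relu")
        expected = dense_gcn_oracle(S.toarray(), W, lambda x: np.maximum(x, 0))
        np.testing.assert_allclose(H, expected, atol=1e-6)

    def test_dimension_mismatch_names_layer(self):
        S = np.eye(4)
        with pytest.raises(ValueError, match="layer 1"):
            gcn_forward(S, [np.ones((4, 3)), np.ones((5, 2))])


class TestAggregation:
    def test_zero_genotype_gives_zero_embedding(self):
        H = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(
            aggregate_patient_embedding(H, np.zeros(4)), np.zeros(3))

    def test_one_hot_selects_embedding(self):
        H = np.arange(12.0).reshape(4, 3)
        G = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(aggregate_patient_embedding(H, G), H[2])

    def test_explicit_summation(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(4, 5))
        G = np.array([2.0, 1.0, 0.0, 1.0])
        expected = 2 * H[0] + H[1] + H[3]
        np.testing.assert_allclose(aggregate_patient_embedding(H, G), expected,
                                   atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(10, 6))
        g1, g2 = rng.uniform(0, 2, size=(2, 10))
        a, b = 0.7, -1.3
        lhs = aggregate_patient_embedding(H, a * g1 + b * g2)
        rhs = (a * aggregate_patient_embedding(H, g1)
               + b * aggregate_patient_embedding(H, g2))
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_patient_embedding(np.ones((3, 2)), np.ones(4))


class TestBCELoss:
    def test_half_probability_is_ln2(self):
        assert bce_loss(np.array([[1.0]]), np.array([[0.5]])) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_point_nine(self):
        assert bce_loss(np.array([[1.0]]), np.array([[0.9]])) == \
            pytest.approx(-np.log(0.9), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        y = (rng.random((4, 3)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, size=(4, 3))
        total = 0.0
        for i in range(4):
            for j in range(3):
                total += (y[i, j] * np.log(p[i, j])
                          + (1 - y[i, j]) * np.log(1 - p[i, j]))
        assert bce_loss(y, p) == pytest.approx(-total / 4, abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.ones((2, 2)), np.ones((2, 3)))

    def test_constant_predictor_minimized_at_label_mean(self):
        rng = np.random.default_rng(6)
        y = (rng.random((50, 1)) < 0.3).astype(float)
        grid = np.linspace(0.01, 0.99, 99)
        losses = [bce_loss(y, np.full_like(y, c)) for c in grid]
        best = grid[int(np.argmin(losses))]
        assert best == pytest.approx(y.mean(), abs=0.01)


class TestStratifiedSplit:
    def test_published_cohort_arithmetic(self):
        assert split_sizes(485754) == (340027, 48576, 97151)

    def test_small_exact_fractions(self):
        rng = np.random.default_rng(7)
        y = np.ones((100, 1))
        tr, va, te = stratified_split(y, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_partition_of_all_samples(self):
        rng = np.random.default_rng(8)
        y = (rng.random((237, 5)) < 0.2).astype(float)
        tr, va, te = stratified_split(y, seed=1)
        combined = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(combined, np.arange(237))

    def test_prevalence_balanced(self):
        rng = np.random.default_rng(9)
        y = (rng.random((1000, 10)) < rng.uniform(0.05, 0.4, size=10)).astype(float)
        tr, va, te = stratified_split(y, seed=2)
        overall = y.mean(axis=0)
        for part in (tr, va, te):
            dev = np.abs(y[part].mean(axis=0) - overall)
            assert dev.max() <= 0.05

    def test_reproducible(self):
        rng = np.random.default_rng(10)
        y = (rng.random((300, 4)) < 0.2).astype(float)
        a = stratified_split(y, seed=3)
        b = stratified_split(y, seed=3)
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x, z)

    def test_rare_label_warns(self):
        y = np.zeros((50, 2))
        y[0, 0] = 1.0
        y[:25, 1] = 1.0
        with pytest.warns(UserWarning, match="fewer users"):
            stratified_split(y, seed=4)

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            split_sizes(100, (0.5, 0.2, 0.2))


@pytest.fixture(scope="module")
def tiny_sim():
    return simulate(SimConfig(n_patients=600, n_genes=10, n_drugs=4,
                              n_diseases=2, seed=21))


class TestEstimators:
    def test_baseline_parameter_count(self):
        m = LogisticUsageClassifier()
        params = m._init_params(np.random.default_rng(0), 5, 2)
        assert sum(v.size for v in params.values()) == 5 * 2 + 2

    def test_gcn_and_random_have_identical_shapes(self, tiny_sim):
        sg, X, Y, _ = tiny_sim
        shapes = {}
        for kind in ("gcn", "gcn-random"):
            m = build_model(kind, graph=sg.graph, feature_ids=X.feature_ids,
                            random_state=0, max_epochs=1, batch_size=256)
            m.fit(X.values, Y.values)
            shapes[kind] = {k: v.shape for k, v in m.params_.items()}
        assert shapes["gcn"] == shapes["gcn-random"]

    def test_all_kinds_emit_probability_matrix(self, tiny_sim):
        sg, X, Y, _ = tiny_sim
        for kind in ("baseline", "dnn", "gcn", "gcn-random"):
            extra = ({"graph": sg.graph, "feature_ids": X.feature_ids}
                     if kind.startswith("gcn") else {})
            m = build_model(kind, random_state=0, max_epochs=2,
                            batch_size=256, **extra)
            m.fit(X.values, Y.values)
            p = m.predict_proba(X.values[:17])
            assert p.shape == (17, Y.n_medications)
            assert ((p > 0) & (p < 1)).all()

    def test_gcn_kind_requires_graph(self):
        with pytest.raises(ValueError, match="graph"):
            build_model("gcn")
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("svm")

    def test_training_reduces_loss_on_separable_toy(self):
        X = np.vstack([np.zeros((10, 2)), np.tile([2.0, 2.0], (10, 1))])
        y = np.vstack([np.zeros((10, 1)), np.ones((10, 1))])
        m = LogisticUsageClassifier(max_epochs=80, patience=80, batch_size=4,
                                    random_state=0)
        m.fit(X, y, X_val=X, y_val=y)
        assert m.history_["train_loss"][-1] < m.history_["train_loss"][0]

    def test_checkpoint_is_validation_argmin(self, tiny_sim):
        sg, X, Y, _ = tiny_sim
        splits = stratified_split(Y, seed=0)
        m = build_model("dnn", random_state=0, batch_size=128, max_epochs=30,
                        patience=30)
        m, hist = train(m, X.values, Y.values, splits)
        assert m.best_epoch_ == int(np.argmin(hist["val_loss"])) + 1
        assert m.best_val_loss_ == pytest.approx(min(hist["val_loss"]))

    def test_fixed_seed_reproduces_history(self, tiny_sim):
        sg, X, Y, _ = tiny_sim
        runs = []
        for _ in range(2):
            m = build_model("gcn", graph=sg.graph, feature_ids=X.feature_ids,
                            random_state=5, max_epochs=5, batch_size=256)
            m.fit(X.values, Y.values)
            runs.append(m.history_["val_loss"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_checkpoint_roundtrip(self, tiny_sim, tmp_path):
        sg, X, Y, _ = tiny_sim
        m = build_model("dnn", random_state=1, max_epochs=3, batch_size=256)
        m.fit(X.values, Y.values)
        before = m.predict_proba(X.values[:5])
        m.save(tmp_path / "w.npz", tmp_path / "w.json")
        m2 = build_model("dnn", random_state=1)
        m2.load_weights(tmp_path / "w.npz")
        np.testing.assert_allclose(m2.predict_proba(X.values[:5]), before,
                                   atol=1e-12)


class TestGCNGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """End-to-end joint gradient of graph weights and head vs numeric."""
        sg, X, Y, _ = simulate(SimConfig(n_patients=20, n_genes=3,
                                         variants_per_gene=2, n_haplotypes=0,
                                         n_drugs=2, n_diseases=1, seed=9))
        m = GCNUsageClassifier(graph=sg.graph, feature_ids=X.feature_ids,
                               embedding_dim=4, head_hidden=(3,), random_state=0)
        rng = np.random.default_rng(0)
        m._prepare_fit(rng)
        m.feature_ids = X.feature_ids
        params = m._init_params(rng, X.n_features, Y.n_medications)
        Xb, yb = X.values[:8], Y.values[:8]

        def loss_at(p):
            logits, _ = m._forward(p, Xb)
            probs = sigmoid(logits)
            eps = 1e-7
            probs = np.clip(probs, eps, 1 - eps)
            return -np.sum(yb * np.log(probs)
                           + (1 - yb) * np.log(1 - probs)) / len(yb)

        logits, cache = m._forward(params, Xb)
        d_logits = (sigmoid(logits) - yb) / len(yb)
        grads = m._backward(params, cache, d_logits)

        h = 1e-6
        check_rng = np.random.default_rng(1)
        for name in params:
            flat = params[name].ravel()
            for idx in check_rng.choice(flat.size, size=min(5, flat.size),
                                        replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_at(params)
                flat[idx] = orig - h
                down = loss_at(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * h)
                analytic = grads[name].ravel()[idx]
                assert analytic == pytest.approx(numeric, abs=2e-5), name
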