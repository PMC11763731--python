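"""GNN layers against brute-force oracles, autograd correctness, training."""

import numpy as np
import pytest

from manifoldmri.metrics import evaluate_classification
from manifoldmri.nn.autograd import Tensor, concat
from manifoldmri.nn.layers import (
    adjacency_to_neighbor_lists,
    edges_to_masks,
    gat_forward,
    gcn_forward,
    identity,
    neighbor_mean_matrix,
    normalize_adjacency,
    relu,
    sage_forward,
)
from manifoldmri.nn.models import ModelConfig, build_model
from manifoldmri.nn.training import TrainConfig, train_node_classifier


def random_graph(rng, n, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return A


class TestNormalizeAdjacency:
    def test_single_node(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((1, 1))),
                                   [[1.0]])

    def test_two_nodes_unit_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), 0.5)

    def test_matches_elementwise_formula(self, rng):
        A = random_graph(rng, 7)
        out = normalize_adjacency(A)
        At = A + np.eye(7)
        deg = At.sum(axis=1)
        brute = np.empty((7, 7))
        for i in range(7):
            for j in range(7):
                brute[i, j] = At[i, j] / np.sqrt(deg[i] * deg[j])
        np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_constant_vector_preserved_on_connected_graph(self, rng):
        # D^-1/2 (A+I) D^-1/2 has D^1/2 1 as an eigenvector with eigenvalue 1;
        # propagating a degree-adjusted constant returns it unchanged
        A = np.ones((5, 5)) - np.eye(5)
        out = normalize_adjacency(A)
        v = np.sqrt((A + np.eye(5)).sum(axis=1))
        np.testing.assert_allclose(out @ v, v, atol=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestGcnForward:
    def test_isolated_nodes_identity(self, rng):
        H = rng.random((4, 3))
        A_norm = normalize_adjacency(np.zeros((4, 4)))
        out = gcn_forward(H, A_norm, np.eye(3), activation=identity)
        np.testing.assert_allclose(out, H)

    def test_two_node_averaging(self):
        A_norm = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gcn_forward(H, A_norm, np.eye(2), activation=identity)
        np.testing.assert_allclose(out, 0.5)

    def test_matches_dense_oracle(self, rng):
        H = rng.standard_normal((8, 5))
        A_norm = normalize_adjacency(random_graph(rng, 8))
        W = rng.standard_normal((5, 4))
        out = gcn_forward(H, A_norm, W, activation=relu)
        oracle = np.maximum(A_norm @ H @ W, 0.0)
        np.testing.assert_allclose(out, oracle, atol=1e-10)


class TestGatForward:
    def gat_oracle(self, H, edges, W, a, slope=0.2):
        """Per-node loop over neighborhoods, straight from the definitions."""
        n = H.shape[0]
        neigh = {i: {i} for i in range(n)}
        for i, j in edges:
            neigh[i].add(j)
            neigh[j].add(i)
        HW = H @ W
        f = W.shape[1]
        out = np.zeros_like(HW)
        for i in range(n):
            js = sorted(neigh[i])
            logits = []
            for j in js:
                e = a @ np.concatenate([HW[i], HW[j]])
                logits.append(e if e > 0 else slope * e)
            logits = np.asarray(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            out[i] = sum(al * HW[j] for al, j in zip(alpha, js))
        return out

    def test_self_only_node(self, rng):
        H = rng.random((3, 4))
        W = rng.standard_normal((4, 2))
        a = rng.standard_normal(4)
        out = gat_forward(H, [], [W], [a], activation=identity)
        np.testing.assert_allclose(out, H @ W, atol=1e-12)

    def test_identical_features_give_uniform_attention(self, rng):
        from manifoldmri.nn.layers import gat_attention

        H = np.tile(rng.random(3), (5, 1))
        W = rng.standard_normal((3, 2))
        a = rng.standard_normal(4)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]
        mask = edges_to_masks(edges, 5)
        alpha, _ = gat_attention(H, W, a, mask)
        sizes = mask.sum(axis=1)
        for i in range(5):
            expected = np.where(mask[i], 1.0 / sizes[i], 0.0)
            np.testing.assert_allclose(alpha[i], expected, atol=1e-12)

    def test_rows_sum_to_one_and_matches_oracle(self, rng):
        from manifoldmri.nn.layers import gat_attention

        for _ in range(5):
            n = 7
            H = rng.standard_normal((n, 4))
            A = random_graph(rng, n)
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if A[i, j]]
            W = rng.standard_normal((4, 3))
            a = rng.standard_normal(6)
            mask = edges_to_masks(edges, n)
            alpha, _ = gat_attention(H, W, a, mask)
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-8)
            out = gat_forward(H, edges, [W], [a], activation=identity)
            oracle = self.gat_oracle(H, edges, W, a)
            np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_multihead_concat_and_average(self, rng):
        n = 5
        H = rng.standard_normal((n, 3))
        edges = [(0, 1), (2, 3)]
        Ws = [rng.standard_normal((3, 2)) for _ in range(3)]
        As = [rng.standard_normal(4) for _ in range(3)]
        cat = gat_forward(H, edges, Ws, As, combine="concat",
                          activation=identity)
        avg = gat_forward(H, edges, Ws, As, combine="average",
                          activation=identity)
        singles = [gat_forward(H, edges, [W], [a], activation=identity)
                   for W, a in zip(Ws, As)]
        np.testing.assert_allclose(cat, np.concatenate(singles, axis=1),
                                   atol=1e-12)
        np.testing.assert_allclose(avg, np.mean(singles, axis=0), atol=1e-12)


class TestSageForward:
    def test_self_equal_neighbors_identity(self, rng):
        H = np.tile(rng.random(3), (4, 1))
        W = 0.5 * np.vstack([np.eye(3), np.eye(3)])
        out = sage_forward(H, [[1], [0], [3], [2]], W, activation=identity)
        np.testing.assert_allclose(out, H, atol=1e-12)

    def test_isolated_node_uses_self(self, rng):
        H = rng.random((2, 3))
        W = rng.standard_normal((6, 2))
        out = sage_forward(H, [[], [0]], W, activation=identity)
        np.testing.assert_allclose(
            out[0], np.concatenate([H[0], H[0]]) @ W, atol=1e-12
        )

    def test_matches_per_node_oracle(self, rng):
        n = 9
        H = rng.standard_normal((n, 4))
        A = random_graph(rng, n)
        neigh = adjacency_to_neighbor_lists(A)
        W = rng.standard_normal((8, 5))
        out = sage_forward(H, neigh, W, activation=relu)
        for i in range(n):
            mean = H[neigh[i]].mean(axis=0) if neigh[i] else H[i]
            oracle = np.maximum(np.concatenate([H[i], mean]) @ W, 0.0)
            np.testing.assert_allclose(out[i], oracle, atol=1e-10)


class TestAutogradAgainstNumericalGradients:
    def numerical_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + eps
            fp = f()
            x[idx] = orig - eps
            fm = f()
            x[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
            it.iternext()
        return g

    @pytest.mark.parametrize("arch", ["gcn", "gat", "sage"])
    def test_model_loss_gradients(self, arch, rng):
        from manifoldmri.nn.training import weighted_cross_entropy

        n, f, k = 6, 5, 3
        X = rng.standard_normal((n, f))
        A = random_graph(rng, n)
        y = rng.integers(0, k, size=n)
        cfg = ModelConfig(arch=arch, hidden_units=4, dropout=0.0,
                          heads_layer1=2, heads_layer2=1, n_classes=k)
        model = build_model(f, cfg, seed=0)
        # non-zero head so its gradient check is informative
        model.params["W_out"].data[:] = rng.standard_normal(
            model.params["W_out"].shape) * 0.3
        cache = model.prepare(A)
        weights = np.ones(k)

        def loss_value():
            logits = model.forward(Tensor(X), cache, training=False, rng=rng)
            return float(weighted_cross_entropy(logits, y, weights).data)

        model.zero_grad()
        logits = model.forward(Tensor(X), cache, training=False, rng=rng)
        loss = weighted_cross_entropy(logits, y, weights)
        loss.backward()
        for name, p in model.params.items():
            numeric = self.numerical_grad(loss_value, p.data)
            analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
            np.testing.assert_allclose(analytic, numeric, atol=1e-6,
                                       err_msg=f"{arch}:{name}")


def separable_tensors(rng, n_per=30, d=6, k=4, shift=25.0):
    """Class-pure clique graph with well-separated node features."""
    H, labels, blocks = [], [], []
    for c in range(k):
        mu = np.zeros(d)
        mu[c] = shift * (c + 1)
        H.append(mu + rng.standard_normal((n_per, d)))
        labels += [f"s{c}"] * n_per
        blocks.append(np.arange(c * n_per, (c + 1) * n_per))
    A = np.zeros((k * n_per, k * n_per))
    for idx in blocks:
        A[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(A, 0.0)
    for c in range(k - 1):  # bridges for connectivity
        A[blocks[c][-1], blocks[c + 1][0]] = 1.0
        A[blocks[c + 1][0], blocks[c][-1]] = 1.0
    H = np.vstack(H)
    H -= H.mean(axis=0)  # pipeline features are PCA-centered
    return H, A, np.array(labels)


class TestTraining:
    def test_seed_determinism(self, rng):
        tensors = separable_tensors(rng)
        cfg = ModelConfig.for_arch("gcn", 4)
        p1, h1, r1 = train_node_classifier(tensors, cfg, TrainConfig(seed=3))
        p2, h2, r2 = train_node_classifier(tensors, cfg, TrainConfig(seed=3))
        assert h1.equals(h2)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])

    def test_separable_graph_perfect_gcn(self, rng):
        tensors = separable_tensors(rng)
        _, _, report = train_node_classifier(
            tensors, ModelConfig.for_arch("gcn", 4), TrainConfig(seed=0)
        )
        assert report.accuracy == 1.0

    def test_permuted_labels_near_chance(self, rng):
        H, A, labels = separable_tensors(rng)
        accs = []
        for seed in range(10):
            perm_labels = np.random.default_rng(seed).permutation(labels)
            _, _, report = train_node_classifier(
                (H, A, perm_labels), ModelConfig.for_arch("gcn", 4),
                TrainConfig(seed=seed),
            )
            accs.append(report.accuracy)
        assert 0.10 <= np.mean(accs) <= 0.45

    def test_missing_class_in_split_rejected(self, rng):
        H, A, labels = separable_tensors(rng, n_per=2)
        labels = labels.copy()
        with pytest.raises(ValueError):
            train_node_classifier((H, A, np.where(labels == "s3", "s0", labels)[:len(labels)]),
                                  ModelConfig.for_arch("gcn", 4),
                                  TrainConfig(seed=0))
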