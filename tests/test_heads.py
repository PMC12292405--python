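"""Classifier heads against independent fixed-weight forward-pass oracles."""

import numpy as np
import pytest

from evoslide.graphs import SlideGraph, normalize_adjacency
from evoslide.heads import (
    GCNN,
    ClassicalHead,
    GatedAttentionMIL,
    OneDCNN,
    TransMILHead,
    TwoDCNN,
    classical_features,
    make_head,
)


def np_softmax(z, axis=-1):
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def conv1d_same_loops(x, W, b):
    """Plain-loop 'same' 1-D convolution oracle: x (L, Cin), W (k, Cin, Cout)."""
    L, cin = x.shape
    k, _, cout = W.shape
    pad = k // 2
    out = np.zeros((L, cout))
    for t in range(L):
        for j in range(k):
            src = t + j - pad
            if 0 <= src < L:
                out[t] += x[src] @ W[j]
    return out + b


def conv2d_same_loops(x, W, b):
    H, Wd, cin = x.shape
    kh, kw, _, cout = W.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((H, Wd, cout))
    for i in range(H):
        for j in range(Wd):
            for dy in range(kh):
                for dx in range(kw):
                    si, sj = i + dy - ph, j + dx - pw
                    if 0 <= si < H and 0 <= sj < Wd:
                        out[i, j] += x[si, sj] @ W[dy, dx]
    return out + b


ALL_KINDS = ("onedcnn", "twodcnn", "gcnn", "mil", "transmil")


def _inputs_for(kind, rng, N=6, d=2, B=2):
    mask = np.zeros((B, N))
    mask[:, :4] = 1.0
    X = rng.normal(size=(B, N, d)) * mask[:, :, None]
    if kind in ("onedcnn", "twodcnn"):
        return {"X": X}
    if kind == "gcnn":
        A = np.zeros((N, N))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        A_hat = normalize_adjacency(A, mask[0].astype(bool))
        return {"X": X, "A_hat": np.stack([A_hat] * B), "mask": mask}
    return {"H": X, "mask": mask}


def _make(kind, seed=0):
    if kind == "transmil":
        return TransMILHead(d_in=2, n_positions=6, seed=seed)
    return make_head(kind, d_in=2, seed=seed)


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_output_is_probability_simplex(kind, rng):
    head = _make(kind)
    probs = head.predict_proba(**_inputs_for(kind, rng))
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_zero_weights_give_uniform_probabilities(kind, rng):
    head = _make(kind)
    head.set_zero_weights()
    probs = head.predict_proba(**_inputs_for(kind, rng))
    np.testing.assert_allclose(probs, 0.5, atol=1e-12)


@pytest.mark.parametrize("kind", ["gcnn", "mil", "transmil"])
def test_padded_content_never_changes_masked_head_output(kind, rng):
    head = _make(kind)
    inputs = _inputs_for(kind, rng)
    base = head.predict_proba(**inputs)
    key = "X" if kind == "gcnn" else "H"
    for _ in range(5):
        tampered = dict(inputs)
        noisy = inputs[key].copy()
        noisy[:, 4:, :] = rng.normal(scale=10.0, size=noisy[:, 4:, :].shape)
        tampered[key] = noisy
        np.testing.assert_allclose(head.predict_proba(**tampered), base,
                                   atol=1e-12)


class TestOneDCNNOracle:
    def test_matches_loop_oracle_on_fixed_weights(self):
        rng = np.random.default_rng(0)
        head = OneDCNN(d_in=2, seed=0)
        X = rng.normal(size=(1, 4, 2))
        got = head.predict_proba(X=X)

        h = np.maximum(conv1d_same_loops(X[0], head.W1.data, head.b1.data), 0)
        h = np.maximum(conv1d_same_loops(h, head.W2.data, head.b2.data), 0)
        pooled = np.maximum(h[0::2][:2], h[1::2][:2])  # maxpool size 2
        gap = pooled.mean(axis=0)
        logits = gap @ head.Wd.data + head.bd.data
        np.testing.assert_allclose(got[0], np_softmax(logits), atol=1e-6)


class TestTwoDCNNOracle:
    def test_matches_loop_oracle_on_fixed_weights(self):
        rng = np.random.default_rng(1)
        head = TwoDCNN(d_in=2, seed=1)
        X = rng.normal(size=(1, 4, 2))
        got = head.predict_proba(X=X)

        img = X[0][:, :, None]
        h = np.maximum(conv2d_same_loops(img, head.W1.data, head.b1.data), 0)
        # maxpool 2x2
        H2, W2 = h.shape[0] // 2, h.shape[1] // 2
        pooled = np.zeros((H2, W2, h.shape[2]))
        for i in range(H2):
            for j in range(W2):
                pooled[i, j] = h[2 * i:2 * i + 2, 2 * j:2 * j + 2].max(axis=(0, 1))
        h = np.maximum(conv2d_same_loops(pooled, head.W2.data, head.b2.data), 0)
        gap = h.mean(axis=(0, 1))
        logits = gap @ head.Wd.data + head.bd.data
        np.testing.assert_allclose(got[0], np_softmax(logits), atol=1e-6)


class TestGCNNOracle:
    def test_single_node_reduces_to_mlp(self):
        head = GCNN(d_in=2, seed=2)
        x = np.array([[[0.3, -0.7]]])
        got = head.predict_proba(X=x, A_hat=np.ones((1, 1, 1)),
                                 mask=np.ones((1, 1)))
        h1 = np.maximum(x[0] @ head.W1.data + head.b1.data, 0)
        h2 = np.maximum(h1 @ head.W2.data + head.b2.data, 0)
        logits = h2[0] @ head.Wd.data + head.bd.data
        np.testing.assert_allclose(got[0], np_softmax(logits), atol=1e-9)

    def test_two_node_graph_matches_hand_chain(self):
        head = GCNN(d_in=2, hidden=(2, 2), seed=3)
        A = np.array([[0, 1], [1, 0]])
        A_hat = normalize_adjacency(A)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = head.predict_proba(X=X[None], A_hat=A_hat[None],
                                 mask=np.ones((1, 2)))
        H1 = np.maximum(A_hat @ (X @ head.W1.data + head.b1.data), 0)
        H2 = np.maximum(A_hat @ (H1 @ head.W2.data + head.b2.data), 0)
        logits = H2.mean(axis=0) @ head.Wd.data + head.bd.data
        np.testing.assert_allclose(got[0], np_softmax(logits), atol=1e-9)

    def test_missing_adjacency_rejected(self):
        head = GCNN(d_in=2)
        with pytest.raises(TypeError):
            head.predict_proba(X=np.zeros((1, 3, 2)))


class TestMILOracle:
    def test_scalar_worked_example(self):
        """h = (1, -1), V=1, U=0, w=1 -> e = +-0.5 tanh(1), weights 0.6817/0.3183."""
        head = GatedAttentionMIL(d_in=1, d_att=1, seed=0)
        head.V.data = np.array([[1.0]])
        head.U.data = np.array([[0.0]])
        head.w.data = np.array([[1.0]])
        from evoslide.nn import Tensor

        a = head.attention(Tensor(np.array([[[1.0], [-1.0]]])),
                           Tensor(np.ones((1, 2))))
        np.testing.assert_allclose(a.data[0], [0.6817, 0.3183], atol=1e-4)

    def test_single_real_instance_gets_weight_one(self, rng):
        head = GatedAttentionMIL(d_in=2, seed=1)
        from evoslide.nn import Tensor

        H = rng.normal(size=(1, 4, 2))
        mask = np.array([[1.0, 0.0, 0.0, 0.0]])
        a = head.attention(Tensor(H), Tensor(mask))
        np.testing.assert_allclose(a.data[0, 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(a.data[0, 1:], 0.0, atol=1e-9)

    def test_identical_instances_share_weight_equally(self):
        head = GatedAttentionMIL(d_in=2, seed=2)
        from evoslide.nn import Tensor

        H = np.tile(np.array([0.5, -0.2]), (1, 3, 1))
        a = head.attention(Tensor(H), Tensor(np.ones((1, 3))))
        np.testing.assert_allclose(a.data[0], 1 / 3, atol=1e-12)

    def test_weights_nonnegative_and_sum_to_one(self, rng):
        head = GatedAttentionMIL(d_in=2, seed=3)
        from evoslide.nn import Tensor

        mask = np.array([[1.0, 1.0, 1.0, 0.0]])
        a = head.attention(Tensor(rng.normal(size=(1, 4, 2))), Tensor(mask))
        assert (a.data >= 0).all()
        assert a.data[0, :3].sum() == pytest.approx(1.0)

    def test_all_masked_bag_rejected(self):
        head = GatedAttentionMIL(d_in=2)
        with pytest.raises(ValueError, match="real instance"):
            head.predict_proba(H=np.zeros((1, 3, 2)), mask=np.zeros((1, 3)))


class TestTransMILOracle:
    def test_matches_numpy_step_by_step_attention(self):
        head = TransMILHead(d_in=2, n_positions=2, d_model=4, d_ff=8, seed=4)
        H = np.array([[[0.2, -0.1], [0.4, 0.3]]])
        mask = np.ones((1, 2))
        got = head.predict_proba(H=H, mask=mask)

        p = {k: v.data for k, v in head._params.items()}
        x = H[0] @ p["Win"] + p["bin"]
        x = np.vstack([p["cls"][0, 0], x]) + p["pos"][0, :3]

        def ln(v, g, b, eps=1e-5):
            mu = v.mean(-1, keepdims=True)
            var = ((v - mu) ** 2).mean(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * g + b

        for i in range(2):
            q, k, v = x @ p[f"Wq{i}"], x @ p[f"Wk{i}"], x @ p[f"Wv{i}"]
            scores = q @ k.T / np.sqrt(4)
            att = np_softmax(scores, axis=-1)
            x = ln(x + att @ v @ p[f"Wo{i}"], p[f"g1_{i}"], p[f"beta1_{i}"])
            ff = np.maximum(x @ p[f"F1_{i}"] + p[f"f1b_{i}"], 0) @ p[f"F2_{i}"] + p[f"f2b_{i}"]
            x = ln(x + ff, p[f"g2_{i}"], p[f"beta2_{i}"])
        logits = x[0] @ p["Wd"] + p["bd"]
        np.testing.assert_allclose(got[0], np_softmax(logits), atol=1e-6)

    def test_all_masked_bag_rejected(self):
        head = TransMILHead(d_in=2, n_positions=3)
        with pytest.raises(ValueError, match="real instance"):
            head.predict_proba(H=np.zeros((1, 3, 2)), mask=np.zeros((1, 3)))


class TestClassicalHeads:
    def _graphs(self):
        rng = np.random.default_rng(0)
        graphs = []
        for i in range(12):
            label = int(i >= 6)
            a = label * 5.0 + rng.normal(scale=0.2)
            g = SlideGraph(
                X=np.array([[a, 0.0], [a + 0.2, 0.0]]),
                A=np.zeros((2, 2), dtype=np.int8),
                A_hat=np.eye(2), node_mask=np.ones(2, dtype=bool), n_real=2,
                label=label, slide_id=f"g{i}",
                positions=np.array([[0.0, 0.0], [1.0, 0.0]]),
            )
            graphs.append(g)
        return graphs

    def test_mean_aggregation_values(self):
        graphs = self._graphs()
        feats = classical_features(graphs)
        np.testing.assert_allclose(feats[0], [graphs[0].X[:, 0].mean(), 0.0],
                                   atol=1e-12)

    def test_mean_of_two_nodes(self):
        g = self._graphs()[0]
        g.X = np.array([[1.0, 3.0], [5.0, 7.0]])
        np.testing.assert_allclose(classical_features([g])[0], [3.0, 5.0])

    @pytest.mark.parametrize("kind", ClassicalHead.KINDS)
    def test_fit_predict_separable(self, kind):
        graphs = self._graphs()
        labels = [g.label for g in graphs]
        head = ClassicalHead(kind, seed=0)
        probs = head.fit(graphs, labels).predict_proba(graphs)
        assert ((probs[:, 1] > 0.5).astype(int) == labels).all()
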