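"""Functional model operations against brute-force / hand oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

import mvst
from mvst.model import (assign_labels, attention_coefficients, decode_views,
                        encode_views, fuse, gcn_layer, init_state,
                        normalized_propagation, soft_assign,
                        target_distribution, total_loss, TrainingConfig)
from mvst.types import SpotFeatures, ViewGraph

from conftest import graph_from_dense


def random_graph(rng, n, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return graph_from_dense(A)


# ------------------------------------------------------------------ gcn_layer

def test_isolated_node_identity_propagation():
    g = graph_from_dense([[0.0]])
    H = np.array([[3.0, -2.0]])
    out = gcn_layer(H, g, np.eye(2), activation="identity")
    np.testing.assert_allclose(out, H, atol=1e-12)


def test_two_node_closed_form():
    g = graph_from_dense([[0, 1], [1, 0]])
    H = np.array([[1.0], [0.0]])
    out = gcn_layer(H, g, np.array([[1.0]]), activation="identity")
    # D^{-1/2} G' D^{-1/2} = [[1/2, 1/2], [1/2, 1/2]]
    np.testing.assert_allclose(out, [[0.5], [0.5]], atol=1e-12)


def test_gcn_layer_matches_dense_oracle(rng):
    g = random_graph(rng, 10)
    H = rng.normal(size=(10, 4))
    W = rng.normal(size=(4, 3))
    # step-by-step oracle: normalize, multiply, activate
    Gp = g.dense() + np.eye(10)
    d = Gp.sum(axis=1)
    P = Gp / np.sqrt(np.outer(d, d))
    expected = np.maximum(P @ H @ W, 0)
    np.testing.assert_allclose(gcn_layer(H, g, W), expected, atol=1e-10)


def test_gcn_layer_shape_errors(rng):
    g = random_graph(rng, 5)
    with pytest.raises(ValueError, match="W rows"):
        gcn_layer(rng.normal(size=(5, 4)), g, rng.normal(size=(3, 2)))
    with pytest.raises(ValueError, match="spots"):
        gcn_layer(rng.normal(size=(4, 3)), g, rng.normal(size=(3, 2)))


# ------------------------------------------------------------------ attention

def test_single_neighbor_attention_is_one():
    # node 1's only neighbour beside itself is node 0
    g = graph_from_dense([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
    H = np.array([[1.0], [2.0], [3.0]])
    Y = attention_coefficients(H, g, np.array([0.7]), np.array([-1.3]),
                               np.array([[2.0]]))
    np.testing.assert_allclose(Y.sum(axis=1), 1.0, atol=1e-12)
    # isolated node 2 only has its self-loop
    assert Y[2, 2] == pytest.approx(1.0)


def test_equal_scores_give_uniform_attention(rng):
    g = random_graph(rng, 8, p=0.5)
    H = np.ones((8, 3))
    # t_s = t_r = 0 -> all U equal -> uniform over each neighbour set
    Y = attention_coefficients(H, g, np.zeros(2), np.zeros(2),
                               rng.normal(size=(3, 2)))
    mask = g.dense() + np.eye(8)
    np.testing.assert_allclose(Y, mask / mask.sum(axis=1, keepdims=True),
                               atol=1e-12)


def test_five_node_attention_scalar_oracle(rng):
    g = random_graph(rng, 5, p=0.6)
    H = rng.normal(size=(5, 3))
    W = rng.normal(size=(3, 2))
    t_s = rng.normal(size=2)
    t_r = rng.normal(size=2)
    Y = attention_coefficients(H, g, t_s, t_r, W)
    mask = g.dense() + np.eye(5)
    HW = H @ W
    s = HW @ t_s
    r = HW @ t_r
    expected = np.zeros((5, 5))
    for i in range(5):
        nbrs = np.where(mask[i] > 0)[0]
        u = 1.0 / (1.0 + np.exp(-(s[i] + r[nbrs])))
        e = np.exp(u)
        expected[i, nbrs] = e / e.sum()
    np.testing.assert_allclose(Y, expected, atol=1e-10)
    assert np.all((Y > 0) == (mask > 0))


def test_uniform_attention_equals_mean_aggregation(rng):
    # degenerate-attention limit: t_s = t_r = 0 makes the GCN layer a
    # row-normalized mean over G' neighbourhoods
    g = random_graph(rng, 7, p=0.5)
    H = rng.normal(size=(7, 4))
    W = rng.normal(size=(4, 2))
    Y = attention_coefficients(H, g, np.zeros(2), np.zeros(2), W)
    out = gcn_layer(H, g, W, Y=Y, activation="identity")
    Gp = g.dense() + np.eye(7)
    mean_agg = (Gp / Gp.sum(axis=1, keepdims=True)) @ H @ W
    np.testing.assert_allclose(out, mean_agg, atol=1e-10)


# ----------------------------------------------------------------------- fuse

def test_fuse_selects_single_view(rng):
    Zs = [rng.normal(size=(6, 3)) for _ in range(3)]
    np.testing.assert_array_equal(fuse(Zs, [1.0, 0.0, 0.0]), Zs[0])


def test_fuse_convexity_fixed_point(rng):
    Z = rng.normal(size=(6, 3))
    np.testing.assert_allclose(fuse([Z, Z.copy(), Z.copy()],
                                    [0.2, 0.5, 0.3]), Z, atol=1e-12)


def test_fuse_weighted_sum_oracle(rng):
    Zs = [rng.normal(size=(4, 2)) for _ in range(3)]
    beta = [0.3, 0.3, 0.4]
    expected = 0.3 * Zs[0] + 0.3 * Zs[1] + 0.4 * Zs[2]
    np.testing.assert_allclose(fuse(Zs, beta), expected, atol=1e-12)


def test_fuse_renormalizes_with_warning(rng):
    Zs = [rng.normal(size=(4, 2)) for _ in range(2)]
    with pytest.warns(UserWarning, match="renormalizing"):
        Z = fuse(Zs, [1.0, 1.0])
    np.testing.assert_allclose(Z, 0.5 * Zs[0] + 0.5 * Zs[1], atol=1e-12)


# ---------------------------------------------------------------- soft assign

def test_equidistant_point_splits_evenly():
    Z = np.array([[0.0, 0.0]])
    C = np.array([[1.0, 0.0], [-1.0, 0.0]])
    np.testing.assert_allclose(soft_assign(Z, C), [[0.5, 0.5]], atol=1e-12)


def test_point_at_centroid_dominates_far_centroid():
    Z = np.array([[0.0]])
    C = np.array([[0.0], [1e6]])
    Q = soft_assign(Z, C)
    assert Q[0, 0] > 1 - 1e-10


def test_alpha_one_hand_arithmetic():
    # distances 1 and 2 with alpha=1: kernels 1/2 and 1/5 -> (5/7, 2/7)
    Z = np.array([[0.0]])
    C = np.array([[1.0], [2.0]])
    Q = soft_assign(Z, C, alpha=1.0)
    np.testing.assert_allclose(Q, [[5 / 7, 2 / 7]], atol=1e-12)


def test_soft_assign_rows_sum_to_one(rng):
    Q = soft_assign(rng.normal(size=(40, 5)), rng.normal(size=(4, 5)))
    np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
    assert Q.min() >= 0


def test_soft_assign_rejects_empty_centroids():
    with pytest.raises(ValueError, match="centroid"):
        soft_assign(np.zeros((3, 2)), np.zeros((0, 2)))


# -------------------------------------------------------- target distribution

def test_target_preserves_symmetry():
    Q = np.array([[0.5, 0.5], [0.5, 0.5]])
    np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)


def test_target_hand_arithmetic():
    Q = np.array([[0.9, 0.1], [0.1, 0.9]])  # equal column frequencies
    P = target_distribution(Q)
    np.testing.assert_allclose(P[0], [0.81 / 0.82, 0.01 / 0.82], atol=1e-12)


def test_target_rows_sum_to_one_and_sharpen(rng):
    raw = rng.random((30, 4)) + 1e-3
    rows = raw / raw.sum(axis=1, keepdims=True)
    # stack all cyclic column shifts so every cluster frequency is equal;
    # with equal frequencies P provably sharpens each row of Q
    Q = np.vstack([np.roll(rows, s, axis=1) for s in range(4)])
    P = target_distribution(Q)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(P.max(axis=1) >= Q.max(axis=1) - 1e-9)


def test_target_excludes_empty_cluster_with_warning():
    Q = np.array([[1.0, 0.0], [1.0, 0.0]])
    with pytest.warns(UserWarning, match="empty cluster"):
        P = target_distribution(Q)
    np.testing.assert_allclose(P[:, 1], 0.0)


# ----------------------------------------------------------------------- loss

def test_loss_zero_at_global_minimum(rng):
    X = rng.normal(size=(6, 4))
    Z = rng.normal(size=(6, 3))
    Q = soft_assign(Z, rng.normal(size=(2, 3)))
    L, comps = total_loss(X, [X.copy()] * 3, [Z.copy()] * 3,
                          [Q.copy()] * 3, Q)
    assert L == 0.0
    assert comps["L_e"] == comps["L_gr"] == comps["L_pd"] == 0.0


def test_loss_pair_convention_ordered_pairs():
    Z1 = np.zeros((2, 2))
    Z2 = np.ones((2, 2))  # ||Z1 - Z2||_F = 2
    X = np.zeros((2, 2))
    Q = np.full((2, 2), 0.5)
    _, comps = total_loss(X, [X, X], [Z1, Z2], [Q, Q], Q)
    assert comps["L_gr"] == pytest.approx(8.0)  # 2^2 per ordered pair


def test_loss_component_additivity(rng):
    X = rng.normal(size=(5, 3))
    recons = [rng.normal(size=(5, 3)) for _ in range(2)]
    Zs = [rng.normal(size=(5, 2)) for _ in range(2)]
    Qs = [soft_assign(Z, rng.normal(size=(3, 2))) for Z in Zs]
    P = target_distribution(Qs[0])
    L, comps = total_loss(X, recons, Zs, Qs, P, rho=[0.5, 2.0])
    assert L == comps["L_e"] + comps["L_gr"] + comps["L_pd"]
    assert L >= 0


def test_loss_single_view_has_no_consistency_term(rng):
    X = rng.normal(size=(5, 3))
    Z = rng.normal(size=(5, 2))
    Q = soft_assign(Z, rng.normal(size=(2, 2)))
    _, comps = total_loss(X, [rng.normal(size=(5, 3))], [Z], [Q],
                          target_distribution(Q))
    assert comps["L_gr"] == 0.0


# --------------------------------------------------------------------- labels

def test_assign_labels_argmax_and_ties():
    P = np.array([[0.2, 0.7, 0.1], [0.5, 0.5, 0.0]])
    np.testing.assert_array_equal(assign_labels(P), [1, 0])


def test_assign_labels_matches_linear_scan(rng):
    raw = rng.random((50, 6))
    P = raw / raw.sum(axis=1, keepdims=True)
    expected = [int(max(range(6), key=lambda j: row[j])) for row in P]
    np.testing.assert_array_equal(assign_labels(P), expected)


# ------------------------------------------------------------ encode / decode

def _features(X):
    return SpotFeatures(X=X, spot_ids=[str(i) for i in range(len(X))],
                        hvg_mask=np.ones(X.shape[1], bool),
                        pca_components=X.shape[1])


def test_encode_views_returns_one_embedding_per_active_view(rng):
    X = rng.normal(size=(10, 6))
    g1 = random_graph(rng, 10)
    g2 = graph_from_dense(random_graph(rng, 10).dense(), "histology", 1)
    cfg = TrainingConfig(gcn_dims=(4,), latent_dim=3)
    state = init_state(6, [g1, g2], cfg, rng)
    embs = encode_views(_features(X), [g1, g2], state)
    assert [e.view_name for e in embs] == ["spatial", "histology"]
    assert all(e.Z.shape == (10, 3) for e in embs)
    for e in embs:
        np.testing.assert_allclose(e.Y.sum(axis=1), 1.0, atol=1e-6)


def test_zero_weights_give_zero_embeddings(rng):
    X = rng.normal(size=(8, 5))
    g = random_graph(rng, 8)
    cfg = TrainingConfig(gcn_dims=(4,), latent_dim=3, projection="linear")
    state = init_state(5, [g], cfg, rng)
    for lp in state.encoder["spatial"]:
        lp.W[:] = 0
    embs = encode_views(_features(X), [g], state, projection="linear")
    np.testing.assert_allclose(embs[0].Z, 0.0, atol=1e-12)


def test_single_layer_encoder_equals_gcn_layer_oracle(rng):
    X = rng.normal(size=(4, 3))
    g = random_graph(rng, 4)
    cfg = TrainingConfig(gcn_dims=(2,), latent_dim=2, projection="linear",
                         attention=False)
    state = init_state(3, [g], cfg, rng)
    embs = encode_views(_features(X), [g], state, attention=False,
                        projection="linear")
    H_oracle = gcn_layer(X, g, state.encoder["spatial"][0].W,
                         activation="identity")
    np.testing.assert_allclose(embs[0].H, H_oracle, atol=1e-10)
    np.testing.assert_allclose(embs[0].Z, H_oracle @ state.proj["spatial"],
                               atol=1e-10)


def test_orthogonal_encoder_transpose_decoder_reconstructs(rng):
    # self-loop-only graph: propagation is the identity
    n, d = 6, 4
    g = graph_from_dense(np.zeros((n, n)))
    X = rng.normal(size=(n, d))
    cfg = TrainingConfig(gcn_dims=(d,), latent_dim=d, projection="linear")
    state = init_state(d, [g], cfg, rng)
    Worth = np.linalg.qr(rng.normal(size=(d, d)))[0]
    state.encoder["spatial"][0].W = Worth
    state.proj["spatial"] = np.eye(d)
    state.inv_proj["spatial"] = np.eye(d)
    state.decoder["spatial"] = [Worth.T]
    embs = encode_views(_features(X), [g], state, attention=False,
                        projection="linear")
    recons = decode_views(embs, [g], state, projection="linear")
    np.testing.assert_allclose(recons[0], X, atol=1e-10)


def test_decoder_output_shape_matches_input(rng):
    X = rng.normal(size=(9, 7))
    g = random_graph(rng, 9)
    cfg = TrainingConfig(gcn_dims=(5, 3), latent_dim=2)
    state = init_state(7, [g], cfg, rng)
    embs = encode_views(_features(X), [g], state)
    recons = decode_views(embs, [g], state)
    assert recons[0].shape == X.shape


def test_linear_autoencoder_matches_matrix_product_oracle(rng):
    # one encoder/decoder pair, linear activations, explicit products
    n, d = 5, 3
    g = random_graph(rng, n)
    X = rng.normal(size=(n, d))
    cfg = TrainingConfig(gcn_dims=(d,), latent_dim=d, projection="linear",
                         attention=False)
    state = init_state(d, [g], cfg, rng)
    P = normalized_propagation(g)
    W_enc = state.encoder["spatial"][0].W
    expected = (P @ ((P @ X @ W_enc) @ state.proj["spatial"]
                     @ state.inv_proj["spatial"]) @ state.decoder["spatial"][0])
    embs = encode_views(_features(X), [g], state, attention=False,
                        projection="linear")
    recons = decode_views(embs, [g], state, projection="linear")
    np.testing.assert_allclose(recons[0], expected, atol=1e-10)
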