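"""Multi-view graph convolutional autoencoder with attention and a
Student-t deep-embedded-clustering head.

One graph convolutional autoencoder per view shares the node-attribute
matrix X. Each encoder layer computes

    H^(l) = sigma( D^{-1/2} (G + I) D^{-1/2} H^(l-1) W^(l) )

and, when attention is enabled, replaces the symmetric-normalized
propagation operator by a row-stochastic attention matrix Y computed
from per-node source/neighbour scores (sigmoid-activated, softmax over
each node's neighbour set including the self-loop). View embeddings
Z_m are fused by a convex combination Z = sum_m beta_m Z_m; a Student-t
kernel against k trainable centroids yields the soft assignment Q, which
is sharpened into the self-training target distribution P. The loss is

    L = L_e + L_gr + L_pd

with L_e the summed per-view reconstruction error ||X - X'_m||_F^2,
L_gr the pairwise view-consistency penalty sum_{i != j} ||Z_i - Z_j||_F^2
(ordered pairs, so every unordered pair counts twice), and L_pd the
distribution-consistency penalty sum_m rho_m ||Q_m - P||_F^2. Training
runs in two phases: reconstruction-only pretraining, then k-means
centroid initialization on the fused embedding followed by joint
training with P refreshed on a fixed interval and treated as a constant
target (no gradient through P).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, constant, masked_softmax_attention, parameter
from .types import SpotFeatures, ViewGraph

__all__ = [
    "TrainingConfig",
    "LayerParams",
    "ModelState",
    "ViewEmbedding",
    "DomainAssignment",
    "normalized_propagation",
    "gcn_layer",
    "attention_coefficients",
    "encode_views",
    "decode_views",
    "fuse",
    "soft_assign",
    "target_distribution",
    "total_loss",
    "assign_labels",
    "fit",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- config

@dataclass
class TrainingConfig:
    """Hyperparameters of the model and its two-phase training loop."""

    seed: int = 0
    gcn_dims: tuple[int, ...] = (256, 64)
    latent_dim: int = 64
    projection: str = "tanh"  # tanh | linear
    attention: bool = True
    lr_pretrain: float = 1e-3
    lr_joint: float = 1e-4
    epochs_pretrain: int = 200
    epochs_joint: int = 200
    p_refresh: int = 20
    beta: tuple[float, ...] | None = None  # None -> uniform over active views
    rho: float | tuple[float, ...] = 1.0
    alpha: float = 1.0
    kmeans_restarts: int = 20
    early_stop_tol: float | None = None


@dataclass
class LayerParams:
    """One encoder GCN layer: weight matrix plus attention score vectors."""

    W: np.ndarray
    t_s: np.ndarray
    t_r: np.ndarray


@dataclass
class ModelState:
    """All trainable parameters of the multi-view model."""

    views: list[str]
    encoder: dict[str, list[LayerParams]]
    proj: dict[str, np.ndarray]
    inv_proj: dict[str, np.ndarray]
    decoder: dict[str, list[np.ndarray]]
    beta: np.ndarray
    rho: np.ndarray
    alpha: float
    centroids: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.min() < 0 or abs(self.beta.sum() - 1.0) > 1e-8:
            raise ValueError("fusion weights must be non-negative and sum to 1")


@dataclass
class ViewEmbedding:
    """Per-view encoder outputs."""

    view_name: str
    H: np.ndarray          # final graph embedding H_m
    Z: np.ndarray          # low-dimensional view embedding Z_m
    Y: np.ndarray | None   # attention coefficients of the last layer


@dataclass
class DomainAssignment:
    """Fused embedding, soft/target distributions and hard labels."""

    Z: np.ndarray
    Q: np.ndarray
    Q_views: dict[str, np.ndarray]
    P: np.ndarray
    labels: np.ndarray


# ----------------------------------------------------------- functional layer

def normalized_propagation(graph: ViewGraph) -> np.ndarray:
    """Dense symmetric-normalized operator D^{-1/2} (G + I) D^{-1/2}."""
    G = graph.dense() + np.eye(graph.n_spots)
    d = G.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return G * inv_sqrt[:, None] * inv_sqrt[None, :]


def _activate(H: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(H, 0)
    if activation in ("identity", "linear"):
        return H
    if activation == "tanh":
        return np.tanh(H)
    raise ValueError(f"unknown activation {activation!r}")


def gcn_layer(H_prev: np.ndarray, graph: ViewGraph, W: np.ndarray,
              Y: np.ndarray | None = None,
              activation: str = "relu") -> np.ndarray:
    """One graph-convolution layer.

    Propagates with the symmetric-normalized operator, or with the
    row-stochastic attention matrix `Y` when given.
    """
    H_prev = np.asarray(H_prev, dtype=float)
    if H_prev.shape[0] != graph.n_spots:
        raise ValueError(
            f"H has {H_prev.shape[0]} rows but graph has {graph.n_spots} spots")
    if H_prev.shape[1] != W.shape[0]:
        raise ValueError(
            f"H columns {H_prev.shape[1]} do not match W rows {W.shape[0]}")
    P = normalized_propagation(graph) if Y is None else np.asarray(Y)
    return _activate(P @ H_prev @ W, activation)


def attention_coefficients(H: np.ndarray, graph: ViewGraph, t_s: np.ndarray,
                           t_r: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Attention matrix Y on the self-loop-augmented edge pattern.

    Per-node scores s = H W t_s (own node) and r = H W t_r (neighbour)
    give U_ij = sigmoid(s_i + r_j) on edges; Y is the row-softmax of U
    over each node's neighbour set (including the self-loop).
    """
    H = np.asarray(H, dtype=float)
    mask = graph.dense() + np.eye(graph.n_spots)
    HW = H @ W
    s = HW @ np.asarray(t_s).reshape(-1, 1)
    r = HW @ np.asarray(t_r).reshape(-1, 1)
    return masked_softmax_attention(constant(s), constant(r), mask).data


def fuse(Z_list: list[np.ndarray], beta) -> np.ndarray:
    """Convex combination of view embeddings, renormalizing beta if needed."""
    beta = np.asarray(beta, dtype=float)
    if len(Z_list) != beta.shape[0]:
        raise ValueError("one beta weight per view embedding required")
    if beta.min() < 0:
        raise ValueError("fusion weights must be non-negative")
    total = beta.sum()
    if abs(total - 1.0) > 1e-8:
        warnings.warn(f"fusion weights sum to {total:.6g}; renormalizing")
        beta = beta / total
    return sum(b * np.asarray(Z) for b, Z in zip(beta, Z_list))


def soft_assign(Z: np.ndarray, centroids: np.ndarray,
                alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment of each spot to each centroid."""
    Z = np.asarray(Z, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] == 0:
        raise ValueError("at least one centroid required")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    kern = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return kern / kern.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened, frequency-corrected self-training target P.

    p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j') with f_j the soft
    cluster frequencies (column sums of Q). Clusters with zero frequency
    are excluded with a warning.
    """
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    if (f == 0).any():
        warnings.warn(f"{int((f == 0).sum())} empty cluster(s) in Q excluded "
                      "from the target distribution")
        f = np.where(f == 0, np.inf, f)
    W = Q * Q / f
    return W / W.sum(axis=1, keepdims=True)


def assign_labels(P: np.ndarray) -> np.ndarray:
    """Hard labels: argmax over clusters, ties to the lowest index."""
    return np.asarray(P).argmax(axis=1)


def total_loss(X: np.ndarray, reconstructions: list[np.ndarray],
               view_Z_list: list[np.ndarray], Q_m_list: list[np.ndarray],
               P: np.ndarray, rho=1.0) -> tuple[float, dict[str, float]]:
    """Composite loss L = L_e + L_gr + L_pd and its components.

    L_gr sums over ordered view pairs (each unordered pair twice).
    """
    X = np.asarray(X, dtype=float)
    L_e = sum(float(((X - Xr) ** 2).sum()) for Xr in reconstructions)
    L_gr = 0.0
    for i in range(len(view_Z_list)):
        for j in range(len(view_Z_list)):
            if i != j:
                L_gr += float(((view_Z_list[i] - view_Z_list[j]) ** 2).sum())
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (len(Q_m_list),))
    L_pd = sum(float(r * ((Qm - P) ** 2).sum())
               for r, Qm in zip(rho_arr, Q_m_list))
    total = L_e + L_gr + L_pd
    return total, {"L_e": L_e, "L_gr": L_gr, "L_pd": L_pd, "L": total}


# ------------------------------------------------------- functional enc / dec

def _encode_one_view_np(X: np.ndarray, graph: ViewGraph,
                        layers: list[LayerParams], proj: np.ndarray,
                        attention: bool, projection: str) -> ViewEmbedding:
    H = np.asarray(X, dtype=float)
    Y = None
    P = None if attention else normalized_propagation(graph)
    for idx, lp in enumerate(layers):
        act = "relu" if idx < len(layers) - 1 else "identity"
        if attention:
            Y = attention_coefficients(H, graph, lp.t_s, lp.t_r, lp.W)
            H = gcn_layer(H, graph, lp.W, Y=Y, activation=act)
        else:
            H = gcn_layer(H, graph, lp.W, Y=P, activation=act)
    Z = _activate(H @ proj, "tanh" if projection == "tanh" else "identity")
    return ViewEmbedding(graph.view_name, H=H, Z=Z, Y=Y)


def encode_views(features: SpotFeatures | np.ndarray,
                 graphs: list[ViewGraph], state: ModelState,
                 attention: bool = True,
                 projection: str = "tanh") -> list[ViewEmbedding]:
    """Encode X through every active view's GCN stack."""
    X = features.X if isinstance(features, SpotFeatures) else np.asarray(features)
    out = []
    for g in graphs:
        if g.n_spots != X.shape[0]:
            raise ValueError(
                f"graph {g.view_name} has {g.n_spots} spots, X has {X.shape[0]}")
        out.append(_encode_one_view_np(X, g, state.encoder[g.view_name],
                                       state.proj[g.view_name], attention,
                                       projection))
    return out


def decode_views(embeddings: list[ViewEmbedding], graphs: list[ViewGraph],
                 state: ModelState, projection: str = "tanh") -> list[np.ndarray]:
    """Mirror each encoder to reconstruct X'_m per view.

    The decoder propagates with the fixed symmetric-normalized operator.
    """
    recons = []
    for emb, g in zip(embeddings, graphs):
        Ws = state.decoder[g.view_name]
        H = emb.Z @ state.inv_proj[g.view_name]
        if projection == "tanh":
            H = _activate(H, "relu")
        P = normalized_propagation(g)
        for idx, W in enumerate(Ws):
            act = "relu" if idx < len(Ws) - 1 else "identity"
            H = gcn_layer(H, g, W, Y=P, activation=act)
        recons.append(H)
    return recons


# ----------------------------------------------------------------- initializer

def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


def init_state(d_in: int, graphs: list[ViewGraph], config: TrainingConfig,
               rng: np.random.Generator | None = None) -> ModelState:
    """Random Glorot-initialized parameters for the active views."""
    rng = rng or np.random.default_rng(config.seed)
    views = [g.view_name for g in graphs]
    M = len(views)
    beta = (np.asarray(config.beta, dtype=float)
            if config.beta is not None else np.full(M, 1.0 / M))
    if beta.shape[0] != M:
        raise ValueError(f"beta has {beta.shape[0]} weights for {M} views")
    if abs(beta.sum() - 1.0) > 1e-8:
        warnings.warn("beta does not sum to 1; renormalizing")
        beta = beta / beta.sum()
    rho = np.broadcast_to(np.asarray(config.rho, dtype=float), (M,)).copy()

    dims = (d_in,) + tuple(config.gcn_dims)
    enc: dict[str, list[LayerParams]] = {}
    proj: dict[str, np.ndarray] = {}
    inv_proj: dict[str, np.ndarray] = {}
    dec: dict[str, list[np.ndarray]] = {}
    for v in views:
        enc[v] = [LayerParams(W=_glorot(rng, dims[l], dims[l + 1]),
                              t_s=_glorot(rng, dims[l + 1], 1),
                              t_r=_glorot(rng, dims[l + 1], 1))
                  for l in range(len(dims) - 1)]
        proj[v] = _glorot(rng, dims[-1], config.latent_dim)
        inv_proj[v] = _glorot(rng, config.latent_dim, dims[-1])
        rev = dims[::-1]
        dec[v] = [_glorot(rng, rev[l], rev[l + 1]) for l in range(len(rev) - 1)]
    return ModelState(views=views, encoder=enc, proj=proj, inv_proj=inv_proj,
                      decoder=dec, beta=beta, rho=rho, alpha=config.alpha)


# ------------------------------------------------------------- training (AD)

class _TensorNet:
    """Autodiff mirror of a ModelState; parameters share no storage with
    the state until :meth:`write_back`."""

    def __init__(self, state: ModelState, graphs: list[ViewGraph],
                 config: TrainingConfig):
        self.state = state
        self.config = config
        self.graphs = {g.view_name: g for g in graphs}
        self.masks = {g.view_name: g.dense() + np.eye(g.n_spots)
                      for g in graphs}
        self.props = {g.view_name: constant(normalized_propagation(g))
                      for g in graphs}
        self.enc = {v: [(parameter(lp.W), parameter(lp.t_s), parameter(lp.t_r))
                        for lp in state.encoder[v]] for v in state.views}
        self.proj = {v: parameter(state.proj[v]) for v in state.views}
        self.inv_proj = {v: parameter(state.inv_proj[v]) for v in state.views}
        self.dec = {v: [parameter(W) for W in state.decoder[v]]
                    for v in state.views}
        self.centroids: Tensor | None = None

    def parameters(self, with_centroids: bool) -> list[Tensor]:
        ps: list[Tensor] = []
        for v in self.state.views:
            for W, t_s, t_r in self.enc[v]:
                ps.append(W)
                if self.config.attention:
                    ps.extend([t_s, t_r])
            ps.extend([self.proj[v], self.inv_proj[v]])
            ps.extend(self.dec[v])
        if with_centroids and self.centroids is not None:
            ps.append(self.centroids)
        return ps

    def encode(self, Xc: Tensor) -> dict[str, Tensor]:
        zs: dict[str, Tensor] = {}
        for v in self.state.views:
            H = Xc
            layers = self.enc[v]
            for idx, (W, t_s, t_r) in enumerate(layers):
                HW = H @ W
                if self.config.attention:
                    s = HW @ t_s
                    r = HW @ t_r
                    Y = masked_softmax_attention(s, r, self.masks[v])
                    out = Y @ HW
                else:
                    out = self.props[v] @ HW
                H = out.relu() if idx < len(layers) - 1 else out
            Z = H @ self.proj[v]
            if self.config.projection == "tanh":
                Z = Z.tanh()
            zs[v] = Z
        return zs

    def decode(self, zs: dict[str, Tensor]) -> dict[str, Tensor]:
        recons: dict[str, Tensor] = {}
        for v in self.state.views:
            H = zs[v] @ self.inv_proj[v]
            if self.config.projection == "tanh":
                H = H.relu()
            Ws = self.dec[v]
            for idx, W in enumerate(Ws):
                H = self.props[v] @ (H @ W)
                if idx < len(Ws) - 1:
                    H = H.relu()
            recons[v] = H
        return recons

    def fused(self, zs: dict[str, Tensor]) -> Tensor:
        Z = None
        for b, v in zip(self.state.beta, self.state.views):
            term = zs[v] * float(b)
            Z = term if Z is None else Z + term
        return Z

    def soft_assign_t(self, Z: Tensor) -> Tensor:
        C = self.centroids
        alpha = self.state.alpha
        z2 = (Z * Z).sum(axis=1, keepdims=True)
        c2 = (C * C).sum(axis=1, keepdims=True).T
        d2 = (z2 - 2.0 * (Z @ C.T) + c2).relu()
        kern = (d2 * (1.0 / alpha) + 1.0).powc(-(alpha + 1.0) / 2.0)
        return kern / kern.sum(axis=1, keepdims=True)

    def write_back(self) -> None:
        for v in self.state.views:
            for lp, (W, t_s, t_r) in zip(self.state.encoder[v], self.enc[v]):
                lp.W, lp.t_s, lp.t_r = W.data, t_s.data, t_r.data
            self.state.proj[v] = self.proj[v].data
            self.state.inv_proj[v] = self.inv_proj[v].data
            self.state.decoder[v] = [W.data for W in self.dec[v]]
        if self.centroids is not None:
            self.state.centroids = self.centroids.data


def _check_finite(value: float, epoch: int, phase: str, comps: dict) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"loss diverged at {phase} epoch {epoch}: components {comps}")


def fit(features: SpotFeatures | np.ndarray, graphs: list[ViewGraph],
        n_domains: int, config: TrainingConfig | None = None
        ) -> tuple[ModelState, DomainAssignment]:
    """Two-phase training; returns the trained state and the assignment.

    Phase 1 pretrains the autoencoders on the reconstruction loss alone;
    phase 2 initializes centroids by k-means on the fused embedding and
    minimizes the full composite loss, refreshing the target distribution
    P every ``config.p_refresh`` epochs. Fully reproducible given
    ``config.seed``.
    """
    from sklearn.cluster import KMeans

    config = config or TrainingConfig()
    X = features.X if isinstance(features, SpotFeatures) else np.asarray(features)
    n = X.shape[0]
    if not graphs:
        raise ValueError("at least one view graph required")
    if n_domains < 2:
        raise ValueError("n_domains must be at least 2")
    if n_domains > n:
        raise ValueError(f"n_domains={n_domains} exceeds {n} spots")
    for g in graphs:
        if g.n_spots != n:
            raise ValueError(f"graph {g.view_name} does not match X rows")

    rng = np.random.default_rng(config.seed)
    state = init_state(X.shape[1], graphs, config, rng)
    net = _TensorNet(state, graphs, config)
    Xc = constant(X.astype(float))

    # ---- phase 1: reconstruction pretraining
    opt = Adam(net.parameters(with_centroids=False), lr=config.lr_pretrain)
    for epoch in range(config.epochs_pretrain):
        zs = net.encode(Xc)
        recons = net.decode(zs)
        loss = None
        for v in state.views:
            term = (Xc - recons[v]).sqnorm()
            loss = term if loss is None else loss + term
        val = float(loss.data)
        _check_finite(val, epoch, "pretrain", {"L_e": val})
        state.history.append({"phase": "pretrain", "epoch": epoch,
                              "L": val, "L_e": val, "L_gr": 0.0, "L_pd": 0.0})
        opt.zero_grad()
        loss.backward()
        opt.step()

    # ---- centroid initialization on the fused embedding
    zs = net.encode(Xc)
    Z0 = net.fused(zs).data
    km = KMeans(n_clusters=n_domains, n_init=config.kmeans_restarts,
                random_state=int(rng.integers(2**31 - 1)))
    km.fit(Z0)
    net.centroids = parameter(km.cluster_centers_)

    # ---- phase 2: joint training
    opt = Adam(net.parameters(with_centroids=True), lr=config.lr_joint)
    P_const: Tensor | None = None
    prev_labels: np.ndarray | None = None
    stop = False
    for epoch in range(config.epochs_joint):
        zs = net.encode(Xc)
        Zf = net.fused(zs)
        if epoch % config.p_refresh == 0:
            Q_now = net.soft_assign_t(Zf).data
            P_np = target_distribution(Q_now)
            P_const = constant(P_np)
            labels_now = assign_labels(P_np)
            if prev_labels is not None and config.early_stop_tol is not None:
                frac = float((labels_now != prev_labels).mean())
                if frac < config.early_stop_tol:
                    stop = True
            prev_labels = labels_now
        recons = net.decode(zs)
        L_e = None
        for v in state.views:
            term = (Xc - recons[v]).sqnorm()
            L_e = term if L_e is None else L_e + term
        L_gr = None
        views = state.views
        for i in range(len(views)):
            for j in range(len(views)):
                if i != j:
                    term = (zs[views[i]] - zs[views[j]]).sqnorm()
                    L_gr = term if L_gr is None else L_gr + term
        L_pd = None
        for r, v in zip(state.rho, views):
            Qm = net.soft_assign_t(zs[v])
            term = ((Qm - P_const) * np.sqrt(float(r))).sqnorm()
            L_pd = term if L_pd is None else L_pd + term
        loss = L_e + L_pd if L_gr is None else L_e + L_gr + L_pd
        comps = {"L_e": float(L_e.data),
                 "L_gr": 0.0 if L_gr is None else float(L_gr.data),
                 "L_pd": float(L_pd.data)}
        val = float(loss.data)
        _check_finite(val, epoch, "joint", comps)
        state.history.append({"phase": "joint", "epoch": epoch, "L": val,
                              **comps})
        if stop:
            log.info("early stop at joint epoch %d", epoch)
            break
        opt.zero_grad()
        loss.backward()
        opt.step()

    net.write_back()

    # ---- final assignment
    embeddings = encode_views(X, graphs, state, attention=config.attention,
                              projection=config.projection)
    Z_list = [e.Z for e in embeddings]
    Zf = fuse(Z_list, state.beta)
    Q = soft_assign(Zf, state.centroids, state.alpha)
    P = target_distribution(Q)
    Q_views = {e.view_name: soft_assign(e.Z, state.centroids, state.alpha)
               for e in embeddings}
    assignment = DomainAssignment(Z=Zf, Q=Q, Q_views=Q_views, P=P,
                                  labels=assign_labels(P))
    return state, assignment
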