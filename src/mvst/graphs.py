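"""Construction of the three spot-similarity graphs.

Each view yields a symmetric binary adjacency over the same spot
ordering: spatial proximity (k nearest spots by Euclidean distance in
the section plane), expression similarity (k-NN in a 50-dimensional PCA
expression space), and histology similarity (k-NN on robust-scaled
texture/intensity features). Directed k-NN results are symmetrized by
union, so an edge exists whenever either endpoint ranks the other among
its k nearest.

Neighbor queries run on exact all-pairs distances with a stable argsort,
which makes tie-breaking deterministic (equidistant spots are taken in
ascending index order) — a property the ball-tree implementations do not
guarantee and that the test oracles rely on.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .types import HistologyFeatures, SpotFeatures, ViewGraph

__all__ = [
    "build_spatial_graph",
    "build_expression_graph",
    "build_histology_graph",
    "knn_adjacency",
    "save_graph",
    "load_graph",
]

log = logging.getLogger(__name__)


def knn_adjacency(points: np.ndarray, k: int) -> sp.csr_matrix:
    """Union-symmetrized k-NN adjacency with stable index tie-breaking."""
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates")
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if n < k + 1:
        warnings.warn(f"only {n} spots; clipping k from {k} to {n - 1}")
        k = n - 1
    if k == 0:
        return sp.csr_matrix((n, n))
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix((np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n))
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    adj.setdiag(0)
    adj.eliminate_zeros()
    return sp.csr_matrix(adj)


def build_spatial_graph(coords: np.ndarray, k: int = 10) -> ViewGraph:
    """Spatial adjacency: each spot linked to its k nearest spots."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be spot x 2")
    return ViewGraph(knn_adjacency(coords, k), "spatial", k)


def build_expression_graph(features: SpotFeatures, k: int = 10,
                           n_pcs_graph: int = 50) -> ViewGraph:
    """Expression similarity: k-NN in the leading 50-D PCA space.

    Uses the leading ``n_pcs_graph`` columns of the already computed PCA
    features, which coincide with a fresh 50-component PCA of the same
    scaled HVG matrix (nested PCA solutions share leading components).
    """
    if n_pcs_graph > features.pca_components:
        raise ValueError(
            f"n_pcs_graph={n_pcs_graph} exceeds {features.pca_components} "
            "available components")
    return ViewGraph(knn_adjacency(features.X[:, :n_pcs_graph], k),
                     "expression", k)


def robust_scale(F: np.ndarray) -> np.ndarray:
    """Per-column (x - median) / IQR scaling; zero-IQR columns get scale 1."""
    F = np.asarray(F, dtype=float)
    med = np.median(F, axis=0)
    q1, q3 = np.percentile(F, [25, 75], axis=0)
    iqr = q3 - q1
    zero = iqr == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} feature column(s) have zero IQR; "
                      "scale set to 1")
        iqr = np.where(zero, 1.0, iqr)
    return (F - med) / iqr


def build_histology_graph(hfeat: HistologyFeatures, k: int = 10) -> ViewGraph:
    """Histology similarity: k-NN on robust-scaled image features."""
    return ViewGraph(knn_adjacency(robust_scale(hfeat.F), k), "histology", k)


# ------------------------------------------------------------------ round-trip

def _spot_hash(spot_ids: list[str]) -> str:
    return hashlib.sha1("\n".join(spot_ids).encode()).hexdigest()


def save_graph(graph: ViewGraph, path: str | Path,
               spot_ids: list[str] | None = None) -> None:
    """Write adjacency as Matrix Market with a JSON sidecar."""
    from scipy.io import mmwrite

    path = Path(path)
    mmwrite(str(path.with_suffix(".mtx")), graph.adj)
    meta = {"view_name": graph.view_name, "k": graph.k,
            "n_spots": graph.n_spots}
    if spot_ids is not None:
        meta["spot_order_sha1"] = _spot_hash(spot_ids)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_graph(path: str | Path,
               spot_ids: list[str] | None = None) -> ViewGraph:
    from scipy.io import mmread

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if spot_ids is not None and "spot_order_sha1" in meta:
        if _spot_hash(spot_ids) != meta["spot_order_sha1"]:
            raise ValueError("spot ordering differs from the saved graph")
    adj = sp.csr_matrix(mmread(str(path.with_suffix(".mtx"))))
    return ViewGraph(adj, meta["view_name"], meta["k"])
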