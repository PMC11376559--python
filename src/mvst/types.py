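"""Core data containers shared across the pipeline.

Spots are always kept in a single, consistent order: the row order of
``SpatialSection.counts`` defines the ordering of coordinates, features,
graph nodes, embeddings and labels everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpatialSection",
    "SpotFeatures",
    "ViewGraph",
    "HistologyFeatures",
    "VIEW_NAMES",
]

VIEW_NAMES = ("spatial", "expression", "histology")


@dataclass
class SpatialSection:
    """A single spatial transcriptomics section.

    Attributes
    ----------
    counts
        spot x gene matrix of non-negative integer UMI counts (dense or
        CSR sparse).
    coords
        spot x 2 array of (row, col) pixel coordinates in the full-resolution
        image frame.
    spot_ids, gene_ids
        Ordered, duplicate-free identifiers matching the count matrix axes.
    image
        Optional H x W x 3 uint8 tissue image registered to ``coords``.
    spot_diameter
        Optional spot diameter in pixels (from the Visium scalefactors file);
        used to auto-size histology patches.
    """

    counts: np.ndarray | sp.spmatrix
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    image: np.ndarray | None = None
    spot_diameter: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("spot_ids/gene_ids lengths do not match counts shape")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        low = self.counts.min() if not sp.issparse(self.counts) else self.counts.data.min(initial=0)
        if low < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        x = self.counts
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


@dataclass
class SpotFeatures:
    """PCA-reduced expression features used as node attributes in every view."""

    X: np.ndarray
    spot_ids: list[str]
    hvg_mask: np.ndarray
    pca_components: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.spot_ids):
            raise ValueError("X rows do not match spot_ids")
        if self.X.shape[1] != self.pca_components:
            raise ValueError("pca_components != X columns")

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]


@dataclass
class ViewGraph:
    """A symmetric binary spot-adjacency graph for one view.

    Self-loops are never stored; the model adds them internally
    (``G' = G + I``).
    """

    adj: sp.csr_matrix
    view_name: str
    k: int

    def __post_init__(self) -> None:
        self.adj = sp.csr_matrix(self.adj)
        n, m = self.adj.shape
        if n != m:
            raise ValueError("adjacency must be square")
        if self.adj.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if (self.adj != self.adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if self.adj.nnz and not np.all(self.adj.data == 1):
            raise ValueError("adjacency must be binary")

    @property
    def n_spots(self) -> int:
        return self.adj.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.adj.todense(), dtype=float)


@dataclass
class HistologyFeatures:
    """Per-spot handcrafted image features (six GLCM texture statistics
    plus mean R/G/B patch intensity)."""

    F: np.ndarray
    spot_ids: list[str]
    feature_names: list[str] = field(
        default_factory=lambda: [
            "contrast",
            "dissimilarity",
            "homogeneity",
            "ASM",
            "entropy",
            "correlation",
            "mean_R",
            "mean_G",
            "mean_B",
        ]
    )

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (len(self.spot_ids), len(self.feature_names)):
            raise ValueError("F shape does not match spot_ids x feature_names")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("histology features must be finite")
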