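"""Reading Visium-style inputs and the expression preprocessing pipeline.

The pipeline follows the conventional spot-based workflow: filter genes
expressed in fewer than `min_cells` spots, library-size normalize to the
median library, log1p, select highly variable genes by dispersion, scale
per gene to zero mean / unit variance, and reduce with PCA. The retained
principal components form the node-attribute matrix X shared by all
graph views.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .types import SpatialSection, SpotFeatures, ViewGraph

__all__ = [
    "read_visium",
    "preprocess",
    "estimate_n_domains",
    "save_features",
    "load_features",
]

log = logging.getLogger(__name__)


class VisiumFormatError(ValueError):
    """Missing or malformed file in a Visium input directory."""


def _find(path: Path, names: list[str]) -> Path | None:
    for name in names:
        for cand in (path / name, path / "spatial" / name,
                     path / f"{name}.gz"):
            if cand.exists():
                return cand
    return None


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_visium(path: str | Path) -> SpatialSection:
    """Read a Space Ranger-style directory into a :class:`SpatialSection`.

    Expects a Matrix Market gene-barcode matrix (genes x barcodes),
    barcode and feature listings, and a tissue-position table; a tissue
    image and scalefactors file are optional. Spots flagged as not under
    tissue are excluded.
    """
    from scipy.io import mmread

    path = Path(path)
    if not path.is_dir():
        raise VisiumFormatError(f"{path} is not a directory")

    mtx = _find(path, ["matrix.mtx", "matrix.mtx.gz"])
    if mtx is None:
        raise VisiumFormatError(f"missing matrix.mtx under {path}")
    barcodes_f = _find(path, ["barcodes.tsv", "barcodes.tsv.gz"])
    if barcodes_f is None:
        raise VisiumFormatError(f"missing barcodes.tsv under {path}")
    features_f = _find(path, ["features.tsv", "features.tsv.gz",
                              "genes.tsv", "genes.tsv.gz"])
    if features_f is None:
        raise VisiumFormatError(f"missing features.tsv under {path}")
    pos_f = _find(path, ["tissue_positions.csv", "tissue_positions_list.csv"])
    if pos_f is None:
        raise VisiumFormatError(f"missing tissue_positions.csv under {path}")

    counts = sp.csr_matrix(mmread(str(mtx)).T)  # -> spots x genes
    barcodes = _read_lines(barcodes_f)
    gene_ids = [ln.split("\t")[0] for ln in _read_lines(features_f)]
    if counts.shape != (len(barcodes), len(gene_ids)):
        raise VisiumFormatError(
            f"matrix shape {counts.shape} inconsistent with "
            f"{len(barcodes)} barcodes x {len(gene_ids)} features")

    pos_cols = ["barcode", "in_tissue", "array_row", "array_col",
                "pxl_row_in_fullres", "pxl_col_in_fullres"]
    head = pd.read_csv(pos_f, nrows=0)
    if "barcode" in head.columns:
        pos = pd.read_csv(pos_f)
    else:  # legacy headerless layout
        pos = pd.read_csv(pos_f, header=None, names=pos_cols)
    pos = pos.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise VisiumFormatError(
            f"{len(missing)} barcodes absent from the positions table "
            f"(first: {missing[0]})")
    pos = pos.loc[barcodes]

    keep = pos["in_tissue"].to_numpy().astype(int) == 1
    counts = counts[keep]
    pos = pos.loc[keep]
    spot_ids = list(pos.index)
    coords = pos[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(float)

    image = None
    for name in ("tissue_image.png", "tissue_hires_image.png",
                 "tissue_image.tif", "tissue_image.jpg"):
        img_f = _find(path, [name])
        if img_f is not None:
            from PIL import Image

            image = np.asarray(Image.open(img_f).convert("RGB"))
            break

    spot_diameter = None
    sf = _find(path, ["scalefactors_json.json"])
    if sf is not None:
        import json

        spot_diameter = json.loads(sf.read_text()).get("spot_diameter_fullres")

    return SpatialSection(counts, coords, spot_ids, gene_ids, image,
                          spot_diameter)


def preprocess(section: SpatialSection, n_hvg: int = 2000, n_pcs: int = 1000,
               min_cells: int = 5, seed: int = 0) -> SpotFeatures:
    """QC / normalization / HVG / PCA pipeline producing node features.

    Genes present in fewer than `min_cells` spots are removed; counts are
    normalized to the median library size and log1p-transformed; the top
    `n_hvg` dispersion-ranked highly variable genes are scaled and
    reduced to `n_pcs` principal components (randomized SVD, seeded).
    `n_pcs` is clipped, with a warning, to what the filtered matrix can
    support.
    """
    if section.n_spots == 0 or section.n_genes == 0:
        raise ValueError("empty section")
    adata = ad.AnnData(
        X=sp.csr_matrix(section.counts_dense().astype(np.float32)),
        obs=pd.DataFrame(index=section.spot_ids),
        var=pd.DataFrame(index=section.gene_ids),
    )
    sc.pp.filter_genes(adata, min_cells=min_cells)
    if adata.n_vars == 0:
        raise ValueError("all genes removed by the min_cells filter")
    kept_after_filter = set(adata.var_names)

    sc.pp.normalize_total(adata)  # target: median library size
    sc.pp.log1p(adata)

    dense = np.asarray(adata.X.todense())
    if np.allclose(dense.var(axis=0), 0):
        raise ValueError("count matrix has no variable genes "
                         "(zero variance everywhere)")

    n_top = min(n_hvg, adata.n_vars)
    if n_top < n_hvg:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {adata.n_vars} surviving genes; "
            f"clipped to {n_top}")
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata)

    max_rank = min(adata.n_obs - 1, adata.n_vars)
    n_comps = min(n_pcs, max_rank)
    if n_comps < n_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds the data rank; clipped to {n_comps}")
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="randomized",
              random_state=seed, zero_center=True)
    X = np.asarray(adata.obsm["X_pca"], dtype=float)

    hvg_set = set(adata.var_names)
    hvg_mask = np.array([g in hvg_set for g in section.gene_ids])
    # genes dropped by the min_cells filter can never be HVG candidates
    assert all(g in kept_after_filter for g in hvg_set)
    return SpotFeatures(X=X, spot_ids=list(section.spot_ids),
                        hvg_mask=hvg_mask, pca_components=n_comps)


def estimate_n_domains(features: SpotFeatures, graph: ViewGraph) -> int:
    """Number of communities found by Louvain on the given graph.

    Used only when the caller does not supply the number of domains.
    """
    if graph.n_spots != features.n_spots:
        raise ValueError("graph and features cover different spot sets")
    if graph.adj.nnz == 0:
        if graph.n_spots > 1:
            warnings.warn("graph has no edges; returning one domain per spot")
        return graph.n_spots
    import igraph

    src, dst = graph.adj.nonzero()
    mask = src < dst
    g = igraph.Graph(n=graph.n_spots,
                     edges=list(zip(src[mask].tolist(), dst[mask].tolist())))
    return len(g.community_multilevel())


def save_features(features: SpotFeatures, path: str | Path) -> None:
    np.savez_compressed(
        path, X=features.X, spot_ids=np.array(features.spot_ids),
        hvg_mask=features.hvg_mask, pca_components=features.pca_components)


def load_features(path: str | Path) -> SpotFeatures:
    with np.load(path, allow_pickle=False) as z:
        return SpotFeatures(X=z["X"], spot_ids=[str(s) for s in z["spot_ids"]],
                            hvg_mask=z["hvg_mask"],
                            pca_components=int(z["pca_components"]))
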