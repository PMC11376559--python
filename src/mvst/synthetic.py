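"""Synthetic Visium-like sections with planted spatial domains.

The generator emulates the three inputs the pipeline consumes — a
domain-structured count matrix, hexagonal-offset grid coordinates, and a
fake stained image whose per-domain colour tint makes histology features
informative of the planted domains. Counts follow a negative-binomial
model with domain-specific marker up-regulation; this is a generative
stand-in that produces realistic overdispersed UMI-like counts so that
every pipeline stage is testable without external downloads.

Two corruption operators mirror common robustness protocols: independent
per-entry dropout (capped at ratio 0.7 — beyond that the matrix becomes
too sparse to carry the feature dimensions the model assumes) and
additive Poisson noise with mean proportional to the mean expression
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .types import SpatialSection

__all__ = [
    "SyntheticSpec",
    "generate_section",
    "apply_dropout",
    "apply_poisson_noise",
    "write_spaceranger_dir",
]

DROPOUT_CAP = 0.7


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic section.

    Defaults describe a desk-scale section: a 30x30 hexagonal grid
    (900 spots), three layered domains, 200 genes of which 50 per domain
    are markers up-regulated 5-fold — strong, spatially coherent expression
    programs with matched image tints.
    """

    n_rows: int = 30
    n_cols: int = 30
    n_domains: int = 3
    domain_geometry: str = "layered"  # layered | blocks | voronoi
    n_genes: int = 200
    n_marker_genes_per_domain: int = 50
    marker_fold_change: float = 5.0
    base_mean: float = 2.0
    dispersion: float = 0.5
    libsize_sigma: float = 0.2
    spot_spacing_px: float = 20.0
    image_domain_tint: np.ndarray | None = None
    image_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains > self.n_rows * self.n_cols:
            raise ValueError("more domains than spots")
        for name in ("n_genes", "n_marker_genes_per_domain", "marker_fold_change",
                     "base_mean", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.domain_geometry not in ("layered", "blocks", "voronoi"):
            raise ValueError(f"unknown geometry {self.domain_geometry!r}")


def _hex_grid(n_rows: int, n_cols: int, spacing: float) -> np.ndarray:
    """Hexagonal-offset grid in (row, col) pixel coordinates."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    y = rr * spacing * np.sqrt(3) / 2
    x = cc * spacing + (rr % 2) * spacing / 2
    return np.column_stack([y.ravel(), x.ravel()]).astype(float)


def _domain_labels(spec: SyntheticSpec, coords: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    k = spec.n_domains
    if spec.domain_geometry == "layered":
        # contiguous horizontal bands of rows
        rows = np.repeat(np.arange(spec.n_rows), spec.n_cols)
        return np.minimum(rows * k // spec.n_rows, k - 1)
    if spec.domain_geometry == "blocks":
        rows = np.repeat(np.arange(spec.n_rows), spec.n_cols)
        cols = np.tile(np.arange(spec.n_cols), spec.n_rows)
        side = int(np.ceil(np.sqrt(k)))
        bi = rows * side // spec.n_rows
        bj = cols * side // spec.n_cols
        return (bi * side + bj) % k
    # voronoi: nearest of k random seed points
    centers = coords[rng.choice(coords.shape[0], size=k, replace=False)]
    d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def _render_image(spec: SyntheticSpec, coords: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fake H&E-like image: pink background, one tint per domain."""
    base = np.array([205.0, 160.0, 190.0])
    if spec.image_domain_tint is not None:
        tints = np.asarray(spec.image_domain_tint, dtype=float)
    else:
        tint_rng = np.random.default_rng(spec.seed + 1)
        tints = tint_rng.uniform(-45, 45, size=(spec.n_domains, 3))
    pad = spec.spot_spacing_px
    h = int(np.ceil(coords[:, 0].max() + 2 * pad))
    w = int(np.ceil(coords[:, 1].max() + 2 * pad))
    img = np.tile(base, (h, w, 1))
    # paint a tinted square around each spot
    half = spec.spot_spacing_px
    shifted = coords + pad
    for d in range(spec.n_domains):
        pts = shifted[labels == d]
        for y0, x0 in pts:
            ylo, yhi = int(max(y0 - half, 0)), int(min(y0 + half, h))
            xlo, xhi = int(max(x0 - half, 0)), int(min(x0 + half, w))
            img[ylo:yhi, xlo:xhi] += tints[d]
    img += rng.normal(0, spec.image_noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), shifted


def generate_section(spec: SyntheticSpec) -> tuple[SpatialSection, np.ndarray]:
    """Generate a section and its planted domain labels.

    Bit-reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _hex_grid(spec.n_rows, spec.n_cols, spec.spot_spacing_px)
    labels = _domain_labels(spec, coords, rng)
    n = coords.shape[0]

    # gene programs: first k*m genes are markers, disjoint per domain
    k, m = spec.n_domains, spec.n_marker_genes_per_domain
    if k * m > spec.n_genes:
        raise ValueError("marker genes exceed total genes")
    gene_base = rng.gamma(shape=2.0, scale=spec.base_mean / 2.0, size=spec.n_genes)
    fold = np.ones((k, spec.n_genes))
    for d in range(k):
        fold[d, d * m:(d + 1) * m] = spec.marker_fold_change
    size_factor = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n))

    mu = size_factor[:, None] * gene_base[None, :] * fold[labels]
    theta = 1.0 / spec.dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p).astype(np.int64)

    img, shifted = _render_image(spec, coords, labels, rng)
    section = SpatialSection(
        counts=counts,
        coords=shifted,
        spot_ids=[f"spot_{i:05d}" for i in range(n)],
        gene_ids=[f"gene_{j:04d}" for j in range(spec.n_genes)],
        image=img,
        spot_diameter=spec.spot_spacing_px,
    )
    return section, labels


def apply_dropout(section: SpatialSection, ratio: float, seed: int) -> SpatialSection:
    """Zero each count independently with probability `ratio` (max 0.7)."""
    if ratio < 0:
        raise ValueError("dropout ratio must be non-negative")
    if ratio > DROPOUT_CAP:
        raise ValueError(
            f"dropout ratio {ratio} exceeds the cap of {DROPOUT_CAP}: beyond it "
            "the expression matrix is too sparse for the model's feature "
            "dimensions"
        )
    counts = section.counts_dense().copy()
    if ratio > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(counts.shape) < ratio
        counts[mask] = 0
    return SpatialSection(counts, section.coords.copy(), list(section.spot_ids),
                          list(section.gene_ids), section.image,
                          section.spot_diameter)


def apply_poisson_noise(section: SpatialSection, level: float, seed: int,
                        noise_mean_mode: str = "grand") -> SpatialSection:
    """Add Poisson noise with mean = level x mean expression.

    ``noise_mean_mode`` selects the reference mean: "grand" uses the grand
    mean of the count matrix (one lambda for all entries); "per_gene" uses
    each gene's mean (a lambda per column).
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    counts = section.counts_dense().copy()
    rng = np.random.default_rng(seed)
    if level > 0:
        if noise_mean_mode == "grand":
            lam = np.full(counts.shape, level * counts.mean())
        elif noise_mean_mode == "per_gene":
            lam = np.broadcast_to(level * counts.mean(axis=0), counts.shape)
        else:
            raise ValueError(f"unknown noise_mean_mode {noise_mean_mode!r}")
        counts = counts + rng.poisson(lam)
    return SpatialSection(counts.astype(np.int64), section.coords.copy(),
                          list(section.spot_ids), list(section.gene_ids),
                          section.image, section.spot_diameter)


def write_spaceranger_dir(section: SpatialSection, path: str | Path,
                          truth_labels: np.ndarray | None = None) -> Path:
    """Write a section as a Space Ranger-style directory.

    Layout: matrix.mtx (genes x barcodes), barcodes.tsv, features.tsv,
    spatial/tissue_positions.csv, spatial/tissue_image.png, and
    spatial/scalefactors_json.json when the spot diameter is known.
    """
    import json

    import pandas as pd
    from PIL import Image
    from scipy.io import mmwrite

    path = Path(path)
    (path / "spatial").mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sp.csr_matrix(section.counts_dense().T))
    (path / "barcodes.tsv").write_text("\n".join(section.spot_ids) + "\n")
    (path / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in section.gene_ids) + "\n")
    pos = pd.DataFrame({
        "barcode": section.spot_ids,
        "in_tissue": 1,
        "array_row": 0,
        "array_col": 0,
        "pxl_row_in_fullres": section.coords[:, 0],
        "pxl_col_in_fullres": section.coords[:, 1],
    })
    pos.to_csv(path / "spatial" / "tissue_positions.csv", index=False)
    if section.image is not None:
        Image.fromarray(section.image).save(path / "spatial" / "tissue_image.png")
    if section.spot_diameter is not None:
        (path / "spatial" / "scalefactors_json.json").write_text(
            json.dumps({"spot_diameter_fullres": section.spot_diameter}))
    if truth_labels is not None:
        pd.DataFrame({"spot_id": section.spot_ids,
                      "domain": np.asarray(truth_labels)}).to_csv(
            path / "truth_labels.csv", index=False)
    return path
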