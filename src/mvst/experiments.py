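"""Desk-scale experiment harness: parameter recovery, corruption
robustness and view ablation on synthetic sections.

These runners bundle the reduced problem sizes the package uses for its
bundled experiments (30x30-grid sections, 50 principal components,
hidden width 32, latent width 16, 50 + 50 training epochs) so that the
examples, the test suite and the acceptance script all execute the same
study conditions. Spatial and histology graphs depend only on the
section geometry and image, so they are cached and shared across
expression-corruption conditions.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .evaluation import adjusted_rand_index
from .graphs import build_expression_graph, build_histology_graph, build_spatial_graph
from .histology import extract_histology_features
from .io_preprocess import preprocess
from .model import TrainingConfig, fit
from .synthetic import SyntheticSpec, apply_dropout, generate_section
from .types import SpatialSection, ViewGraph

__all__ = [
    "desk_spec",
    "desk_training_config",
    "GraphCache",
    "condition_ari",
    "median_ari",
    "dropout_trend",
    "ablation_aris",
]

log = logging.getLogger(__name__)

DESK_N_HVG = 150
DESK_N_PCS = 50
DESK_K = 10


def desk_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reference synthetic study condition: 30x30 grid, 3 layered
    domains, 200 genes, 50 markers/domain at 5-fold up-regulation,
    domain-matched image tints."""
    return SyntheticSpec(seed=seed, **overrides)


def desk_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    cfg = TrainingConfig(seed=seed, gcn_dims=(32,), latent_dim=16,
                         epochs_pretrain=50, epochs_joint=50, p_refresh=10)
    return replace(cfg, **overrides) if overrides else cfg


class GraphCache:
    """Caches the expression-independent views of one section."""

    def __init__(self, section: SpatialSection, k: int = DESK_K):
        self.k = k
        self.spatial = build_spatial_graph(section.coords, k=k)
        self.histology: ViewGraph | None = None
        if section.image is not None:
            hfeat = extract_histology_features(section, patch_px=None)
            self.histology = build_histology_graph(hfeat, k=k)


def condition_ari(section: SpatialSection, truth: np.ndarray,
                  views: tuple[str, ...], seed: int,
                  cache: GraphCache | None = None,
                  config: TrainingConfig | None = None) -> float:
    """Train on one section with the given views/seed; ARI vs truth."""
    cache = cache or GraphCache(section)
    config = config or desk_training_config(seed)
    config = replace(config, seed=seed)
    features = preprocess(section, n_hvg=DESK_N_HVG, n_pcs=DESK_N_PCS,
                          seed=seed)
    graphs: list[ViewGraph] = []
    for v in views:
        if v == "spatial":
            graphs.append(cache.spatial)
        elif v == "expression":
            graphs.append(build_expression_graph(features, k=cache.k,
                                                 n_pcs_graph=DESK_N_PCS))
        elif v == "histology":
            if cache.histology is None:
                raise ValueError("section has no image for the histology view")
            graphs.append(cache.histology)
        else:
            raise ValueError(f"unknown view {v!r}")
    n_domains = int(np.unique(truth).size)
    _, assignment = fit(features, graphs, n_domains, config)
    ari = adjusted_rand_index(truth, assignment.labels)
    log.info("views=%s seed=%d ARI=%.4f", "+".join(views), seed, ari)
    return ari


def median_ari(section: SpatialSection, truth: np.ndarray,
               views: tuple[str, ...], seeds: list[int],
               cache: GraphCache | None = None) -> float:
    cache = cache or GraphCache(section)
    return float(np.median([condition_ari(section, truth, views, s, cache)
                            for s in seeds]))


def dropout_trend(spec: SyntheticSpec, ratios: list[float],
                  seeds: list[int]) -> dict[float, float]:
    """Median ARI per dropout ratio (corruption applied to counts only;
    the spatial and histology views are shared across ratios)."""
    section, truth = generate_section(spec)
    cache = GraphCache(section)
    out = {}
    for ratio in ratios:
        aris = []
        for seed in seeds:
            corrupted = (section if ratio == 0
                         else apply_dropout(section, ratio, seed=seed + 10_000))
            aris.append(condition_ari(corrupted, truth,
                                      ("spatial", "expression", "histology"),
                                      seed, cache))
        out[ratio] = float(np.median(aris))
    return out


def ablation_aris(spec: SyntheticSpec, seeds: list[int]) -> dict[str, float]:
    """Median ARI of the full model and both two-view variants."""
    section, truth = generate_section(spec)
    cache = GraphCache(section)
    variants = {
        "full": ("spatial", "expression", "histology"),
        "view1&3": ("spatial", "histology"),
        "view2&3": ("expression", "histology"),
    }
    return {name: median_ari(section, truth, views, seeds, cache)
            for name, views in variants.items()}
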