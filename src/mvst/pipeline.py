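"""End-to-end orchestration: section -> features -> graphs -> domains.

This is the library-level entry point the CLI wraps. It wires the full
workflow (preprocess, build the requested view graphs, train, label) and
can write a reproducible artifact directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graphs import (build_expression_graph, build_histology_graph,
                     build_spatial_graph)
from .histology import extract_histology_features
from .io_preprocess import estimate_n_domains, preprocess
from .model import DomainAssignment, ModelState, TrainingConfig, fit
from .types import SpatialSection, SpotFeatures, ViewGraph, VIEW_NAMES

__all__ = ["RunConfig", "run_pipeline", "build_graphs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    views: tuple[str, ...] = VIEW_NAMES
    n_domains: int | None = None  # None -> Louvain estimate
    n_hvg: int = 2000
    n_pcs: int = 1000
    min_cells: int = 5
    k_neighbors: int = 10
    n_pcs_graph: int = 50
    patch_px: int | None = None
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        bad = set(self.views) - set(VIEW_NAMES)
        if bad:
            raise ValueError(f"unknown views {sorted(bad)}")
        if not self.views:
            raise ValueError("at least one view required")


def build_graphs(section: SpatialSection, features: SpotFeatures,
                 config: RunConfig) -> list[ViewGraph]:
    graphs: list[ViewGraph] = []
    n_pcs_graph = min(config.n_pcs_graph, features.pca_components)
    for view in config.views:
        if view == "spatial":
            graphs.append(build_spatial_graph(section.coords,
                                              k=config.k_neighbors))
        elif view == "expression":
            graphs.append(build_expression_graph(features,
                                                 k=config.k_neighbors,
                                                 n_pcs_graph=n_pcs_graph))
        elif view == "histology":
            hfeat = extract_histology_features(section,
                                               patch_px=config.patch_px)
            graphs.append(build_histology_graph(hfeat, k=config.k_neighbors))
    return graphs


def run_pipeline(section: SpatialSection, config: RunConfig | None = None,
                 out_dir: str | Path | None = None
                 ) -> tuple[ModelState, DomainAssignment]:
    """Run preprocess -> graphs -> fit -> labels; optionally write artifacts.

    The artifact directory contains labels.csv, embedding.npz,
    loss_trace.csv and config.json — enough to reproduce the run.
    """
    config = config or RunConfig()
    config.training.seed = config.seed
    log.info("preprocessing %d spots x %d genes", section.n_spots,
             section.n_genes)
    features = preprocess(section, n_hvg=config.n_hvg, n_pcs=config.n_pcs,
                          min_cells=config.min_cells, seed=config.seed)
    log.info("building views: %s", ", ".join(config.views))
    graphs = build_graphs(section, features, config)
    n_domains = config.n_domains
    if n_domains is None:
        n_domains = estimate_n_domains(features, graphs[0])
        log.info("Louvain estimated %d domains", n_domains)
    state, assignment = fit(features, graphs, n_domains, config.training)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"spot_id": features.spot_ids,
                      "domain": assignment.labels}).to_csv(
            out / "labels.csv", index=False)
        np.savez_compressed(out / "embedding.npz", Z=assignment.Z,
                            Q=assignment.Q, P=assignment.P,
                            spot_ids=np.array(features.spot_ids))
        pd.DataFrame(state.history).to_csv(out / "loss_trace.csv", index=False)
        echo = {"version": __version__, "n_domains": int(n_domains),
                **_jsonable(asdict(config))}
        (out / "config.json").write_text(json.dumps(echo, indent=2))
    return state, assignment


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
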