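"""Preprocess a section and build the three spot-similarity graphs.

Counts are filtered, normalized, log-transformed, reduced to principal
components; the three views are k-nearest-neighbour graphs over spatial
position, expression space and histology-patch features.
"""

import mvst
from mvst.io_preprocess import estimate_n_domains

spec = mvst.SyntheticSpec(n_rows=15, n_cols=15, n_genes=120,
                          n_marker_genes_per_domain=30, seed=0)
section, truth = mvst.generate_section(spec)

features = mvst.preprocess(section, n_hvg=100, n_pcs=50)
print(f"node features X: {features.X.shape} "
      f"({int(features.hvg_mask.sum())} HVGs retained)")

spatial = mvst.build_spatial_graph(section.coords, k=10)
expression = mvst.build_expression_graph(features, k=10, n_pcs_graph=50)
hfeat = mvst.extract_histology_features(section, patch_px=None)
histology = mvst.build_histology_graph(hfeat, k=10)

for g in (spatial, expression, histology):
    print(f"{g.view_name:<11} graph: {g.adj.nnz // 2} edges "
          f"(k={g.k}, union-symmetrized)")

# When the caller does not know the number of domains, Louvain on the
# expression graph gives a data-driven estimate.
print(f"Louvain domain estimate: {estimate_n_domains(features, expression)}")
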