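"""Generate a synthetic Visium-like section with planted spatial domains.

The generator emulates the three inputs of the pipeline: a
negative-binomial count matrix with domain-specific marker genes,
hexagonal-offset grid coordinates, and a fake stained image whose
per-domain tint makes histology informative of the domains.
"""

import numpy as np

import mvst

spec = mvst.SyntheticSpec(n_rows=15, n_cols=15, n_domains=3,
                          n_genes=120, n_marker_genes_per_domain=30,
                          marker_fold_change=5.0, seed=0)
section, truth = mvst.generate_section(spec)

print(f"spots:          {section.n_spots}")
print(f"genes:          {section.n_genes}")
print(f"image:          {section.image.shape} uint8")
print(f"domain sizes:   {np.bincount(truth).tolist()}")
print(f"median library: {np.median(section.counts_dense().sum(axis=1)):.0f} UMIs/spot")
# Each spot belongs to one of three horizontal bands; marker genes are
# 5-fold up-regulated inside their band, which is what the model must
# rediscover without seeing `truth`.
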