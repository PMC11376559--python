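"""Identify spatial domains end to end and score them against the
planted truth.

Trains the three-view graph convolutional autoencoder (reconstruction
pretraining, then joint training with the Student-t clustering head) and
reports the adjusted Rand index of the recovered labels.
"""

import numpy as np

import mvst

spec = mvst.SyntheticSpec(n_rows=15, n_cols=15, n_genes=120,
                          n_marker_genes_per_domain=30, seed=0)
section, truth = mvst.generate_section(spec)

config = mvst.RunConfig(
    n_domains=3, n_hvg=100, n_pcs=50, seed=0,
    training=mvst.TrainingConfig(seed=0, gcn_dims=(32,), latent_dim=16,
                                 epochs_pretrain=50, epochs_joint=50,
                                 p_refresh=10),
)
state, assignment = mvst.run_pipeline(section, config)

ari = mvst.adjusted_rand_index(truth, assignment.labels)
print(f"recovered domains: {len(np.unique(assignment.labels))}")
print(f"ARI vs planted truth: {ari:.3f}")
print(f"final loss components: "
      f"L_e={state.history[-1]['L_e']:.1f} "
      f"L_gr={state.history[-1]['L_gr']:.3f} "
      f"L_pd={state.history[-1]['L_pd']:.3f}")
# ARI of 1.0 means the partition matches the planted domains exactly up
# to relabeling; values above ~0.9 indicate near-perfect recovery.
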