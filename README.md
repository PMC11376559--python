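# mvst — multi-view spatial-domain identification for spatial transcriptomics

`mvst` clusters the spots of a spot-based spatial transcriptomics section
(10X Visium) into **spatial domains** — contiguous tissue regions with
coherent gene expression and histology — by learning a single clustering
embedding that is consistent across three views of the section:

1. **spatial proximity** — a k-NN graph over spot coordinates,
2. **expression similarity** — a k-NN graph in a 50-D PCA expression space,
3. **histology similarity** — a k-NN graph over handcrafted image features
   (GLCM texture statistics + mean RGB of the patch around each spot).

Each view feeds a graph convolutional autoencoder with per-layer attention:

    H⁽ˡ⁾ = σ( D^{−1/2} (G_m + I) D^{−1/2} H⁽ˡ⁻¹⁾ W⁽ˡ⁾ )

(attention, when enabled, replaces the normalized propagation operator by a
row-stochastic softmax over each node's neighbour set). The view embeddings
are fused, Z = Σ_m β_m Z_m, and a Student-t kernel against k trainable
centroids yields a soft assignment Q, sharpened into a self-training target
P with p_ij ∝ q_ij²/f_j. Training minimizes

    L = Σ_m‖X − X′_m‖²_F  +  Σ_{i≠j}‖Z_i − Z_j‖²_F  +  Σ_m ρ_m‖Q_m − P‖²_F

after reconstruction-only pretraining; hard labels are the row argmax of P.
Agreement with reference annotations is scored with the adjusted Rand index
(ARI). See `docs/methods.md` for the full model description.

It is intended for computational biologists analysing Visium sections who
want domain calls that use the stained image as a first-class signal rather
than ignoring it.

## Worked example

```bash
python examples/03_identify_domains.py
```

```
recovered domains: 3
ARI vs planted truth: 0.973
final loss components: L_e=47090.0 L_gr=19629.230 L_pd=175.134
```

The script simulates a 15×15 hexagonal-grid section with three planted
layered domains (30 marker genes per domain, 5-fold up-regulated, matched
image tints), trains the full three-view model at desk scale, and scores the
recovered partition. ARI = 0.973 means the labels match the planted domains
nearly exactly up to relabeling (1.0 is a perfect match). The loss
components show where the optimum settles: `L_e` is the irreducible
reconstruction noise floor of the counts, `L_gr` the residual geometric gap
between the three view embeddings, and the small `L_pd` indicates the
per-view soft assignments agree closely with the shared target
distribution.

The other examples cover simulation (`01`), preprocessing and graph
construction (`02`), corruption robustness (`04`) and view ablation (`05`).

On real data, point the CLI at a Space Ranger-style directory
(Matrix Market counts + barcodes/features + tissue positions, optional
H&E image):

```bash
mvst run --input /path/to/section --n-domains 7 --seed 0 --out out/
mvst evaluate --truth annotations.csv --pred out/labels.csv
```

`mvst simulate`, `mvst corrupt` and `mvst ablate` expose the synthetic
generator, the corruption operators and the two-view ablation variants.

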