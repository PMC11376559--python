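# Methods

## Problem and model

Spot-based spatial transcriptomics assays (10X Visium) measure a gene
expression profile at each barcoded spot together with the spot's position in
the tissue and, usually, an H&E-stained image of the section. A *spatial
domain* is a contiguous tissue region with coherent expression and histology.
This package identifies spatial domains unsupervised by treating the section
as three graphs over the same spots and learning a single clustering embedding
consistent across them.

### Views

Each view is a symmetric binary k-nearest-neighbour graph (default k = 10,
union symmetrization: an edge exists when either endpoint ranks the other in
its top k):

1. **spatial** — Euclidean distance between spot coordinates;
2. **expression** — Euclidean distance in a 50-dimensional PCA expression
   space (the leading 50 columns of the node-feature PCA; a nested PCA of the
   same matrix shares leading components, so no second decomposition is run);
3. **histology** — Euclidean distance on robust-scaled per-spot image
   features: six gray-level co-occurrence (GLCM) statistics of the
   CLAHE-equalized grayscale patch around the spot (contrast, dissimilarity,
   homogeneity, angular second moment, entropy, correlation) plus the raw
   patch's mean R/G/B intensities.

Self-loops are never stored in a view graph; the model adds them internally.

### Node features

All views share one node-attribute matrix X: genes present in fewer than 5
spots are removed, counts are library-size-normalized to the median library
and log1p-transformed, the top 2000 dispersion-ranked highly variable genes
are scaled to zero mean / unit variance, and PCA retains the leading
components (default 1000, clipped to the data rank with a warning for small
sections).

### Architecture

Per view m, a graph convolutional encoder stacks layers

    H^(l) = sigma( D^{-1/2} (G_m + I) D^{-1/2} H^(l-1) W^(l) ),

ReLU on hidden layers, identity on the last. With attention enabled
(default), the propagation operator of each layer is replaced by a
row-stochastic attention matrix Y: per-node scores s = H W t_s (own node) and
r = H W t_r (neighbour) give U_ij = sigmoid(s_i + r_j) on the self-loop-
augmented edge pattern, and Y is the row-softmax of U over each node's
neighbour set. With t_s = t_r = 0 this degenerates to a uniform mean over
neighbourhoods. A dense projection (tanh by default) maps the final graph
embedding H_m to the view embedding Z_m; the fused clustering embedding is
the convex combination Z = Σ_m β_m Z_m. Decoders mirror the encoder
dimensions (dense inverse projection, then graph convolutions back to the
input width) and propagate with the fixed symmetric-normalized operator;
decoder weights are independent of encoder weights.

### Clustering head and loss

A Student-t kernel with α degrees of freedom compares each fused embedding
z_i to k trainable centroids μ_j:

    q_ij ∝ (1 + ||z_i − μ_j||² / α)^{−(α+1)/2},   rows normalized.

The self-training target sharpens Q and corrects for cluster frequency
f_j = Σ_i q_ij:

    p_ij ∝ q_ij² / f_j,   rows normalized.

The frequency index is read as a column sum (cluster frequency), the standard
deep-embedded-clustering construction. The loss is L = L_e + L_gr + L_pd:

* L_e = Σ_m ||X − X'_m||²_F — per-view reconstruction;
* L_gr = Σ_{i≠j} ||Z_i − Z_j||²_F — geometric consistency over **ordered**
  view pairs (each unordered pair counts twice; the constant factor is
  absorbed into the term's weight and documented so tests are exact);
* L_pd = Σ_m ρ_m ||Q_m − P||²_F — distribution consistency, where Q_m is the
  Student-t assignment of Z_m against the shared centroids.

Training has two phases: (1) pretraining on L_e alone (Adam, lr 1e-3, 200
epochs by default); (2) k-means (20 restarts, seeded) on the fused Z
initializes the centroids, then joint training on L (Adam, lr 1e-4, 200
epochs), refreshing P every 20 epochs and treating it as a constant target
(no gradient through P). Hard labels are the row argmax of P, ties to the
lowest index. An optional early stop triggers when the label-change fraction
between consecutive P refreshes falls below a tolerance; it is off by
default.

The network and its training run on a small reverse-mode automatic
differentiation engine over dense NumPy arrays (`mvst.autodiff`); the
attention softmax is a single fused operator with a hand-derived backward
pass, which keeps full-batch training on ~10³ spots in seconds per epoch on
one CPU.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k_neighbors | 10 | neighbours per spot in every view graph |
| n_hvg | 2000 | highly variable genes retained |
| n_pcs | 1000 | principal components in X (clipped to rank) |
| n_pcs_graph | 50 | expression-graph dimensionality |
| gcn_dims | (256, 64) | encoder layer widths |
| latent_dim | 64 | view/fused embedding width d_z |
| β | uniform | view fusion weights (renormalized if not summing to 1) |
| ρ_m | 1 | per-view weight of the distribution-consistency term |
| α | 1 | Student-t degrees of freedom |
| attention | on | per-layer attention propagation (off restores the plain symmetric-normalized operator) |
| patch_px | 50 / auto | histology patch side; auto uses the Visium spot diameter when the scalefactors file is present |

GLCM parameters: 64 gray levels, distance 1, angles {0°, 45°, 90°, 135°}
averaged, symmetric and normalized matrix; entropy −Σ p log₂ p over nonzero
cells. CLAHE clip limit 0.01 on the [0, 1] grayscale patch. These are
package choices; they are exposed rather than hidden.

## Numerical choices and degenerate inputs

* k-NN queries use exact all-pairs distances with a stable argsort:
  equidistant spots are taken in ascending index order, making graph
  construction fully deterministic (ball-tree backends do not guarantee a tie
  order). Cost is O(n²), negligible at Visium scale.
* Robust scaling of histology features uses linear-interpolation quartiles;
  zero-IQR columns fall back to unit scale with a warning.
* A node whose neighbour set is empty receives a unit self-loop weight in the
  attention matrix.
* Zero-frequency clusters are excluded from the target distribution with a
  warning.
* Squared distances in the Student-t kernel are clamped at zero to absorb
  floating-point cancellation.
* Both partitions collapsing to a single cluster makes the ARI denominator
  0/0; the implementation returns 1 by convention. Spots without a truth
  annotation are excluded from the ARI with a logged count.
* Divergent training (non-finite loss) raises an error naming the phase,
  epoch and loss components.

## Open design points, resolved

* **How attention combines with the GCN layer** is not fixed by the layer
  equations alone: the attention matrix is itself a normalized propagation
  operator, so when enabled it *replaces* the symmetric-normalized operator;
  `attention=False` restores the plain layer.
* **Score attachment**: t_s scores attach to the row (own) node and t_r to
  the column (neighbour) node of each edge.
* **Decoder weights** are independent, not tied transposes.
* **Normalization target and HVG flavour** (median library; dispersion-based
  "seurat" ranking) follow the conventional toolchain defaults.
* **Dropout cap**: corruption ratios above 0.7 are rejected — beyond that the
  matrix is too sparse to carry the model's feature dimensions.
* **Poisson noise mean**: λ = level × grand mean of the count matrix by
  default; a per-gene mode is available (`noise_mean_mode="per_gene"`).

## Synthetic sections: what they emulate and what they do not

The generator plants n_domains spatial domains (layered bands, blocks or
Voronoi cells) on a hexagonal-offset grid, draws counts from a negative
binomial with per-spot lognormal library-size factors and per-domain marker
genes up-regulated by a constant fold change, and renders a fake stained
image with one colour tint per domain plus pixel noise. The reference study
condition used by the bundled experiments is a 30×30 grid (900 spots), 3
layered domains, 200 genes with 50 markers per domain at 5-fold
up-regulation, and domain-matched tints — strong, spatially coherent signal
in *all three* views.

Real sections differ in ways the generator does not emulate: irregular domain
boundaries, gradual expression gradients, spot swapping and diffusion
artifacts, realistic H&E morphology (nuclei, stroma texture), and annotation
noise. Passing the bundled experiments therefore demonstrates that the
implementation recovers well-separated planted structure and degrades
gracefully under corruption; it does not by itself establish accuracy on
real tissue.

## Desk-scale experiment sizes

The bundled experiments (examples, test suite, `scripts/acceptance.py`) run
the reference section at reduced sizes chosen for single-CPU turnaround: 150
HVGs, 50 principal components, one hidden layer of width 32, latent width 16,
50 + 50 training epochs, P refreshed every 10 epochs. Recovery of the planted
domains is insensitive to these widths on the reference condition; the
defaults in `TrainingConfig` remain the full-scale values.

## Known limitations

* Visium-style spot grids only; no support for single-cell-resolution
  platforms.
* Handcrafted histology features (GLCM + mean RGB); no learned image
  embeddings.
* Full-batch dense training: memory grows as O(n²) with the number of spots,
  practical to ~10⁴ spots on a workstation.
* Louvain-based domain-number estimation is a thin convenience; supplying
  the domain count is preferred when it is known.
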