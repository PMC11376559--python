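"""Synthetic-section generator and the two corruption operators."""

import numpy as np
import pytest

import mvst
from mvst.synthetic import DROPOUT_CAP


def test_generation_is_bit_reproducible():
    spec = mvst.SyntheticSpec(n_rows=8, n_cols=8, n_genes=40,
                              n_marker_genes_per_domain=10, seed=42)
    s1, t1 = mvst.generate_section(spec)
    s2, t2 = mvst.generate_section(spec)
    np.testing.assert_array_equal(s1.counts_dense(), s2.counts_dense())
    np.testing.assert_array_equal(s1.image, s2.image)
    np.testing.assert_array_equal(t1, t2)


def test_layered_geometry_forms_contiguous_bands():
    spec = mvst.SyntheticSpec(n_rows=30, n_cols=30, n_genes=30,
                              n_marker_genes_per_domain=10, n_domains=3)
    _, truth = mvst.generate_section(spec)
    rows = np.repeat(np.arange(30), 30)
    # labels are a non-decreasing function of the grid row
    for d in range(3):
        band = rows[truth == d]
        assert band.max() - band.min() == len(np.unique(band)) - 1
    assert np.all(np.diff([truth[rows == r][0] for r in range(30)]) >= 0)


def test_null_fold_change_removes_domain_signal():
    spec = mvst.SyntheticSpec(n_rows=10, n_cols=10, n_genes=60,
                              n_marker_genes_per_domain=15,
                              marker_fold_change=1.0, seed=1)
    section, truth = mvst.generate_section(spec)
    counts = np.log1p(section.counts_dense())

    def separation(labels):
        means = np.array([counts[labels == d].mean(axis=0) for d in range(3)])
        return np.abs(means[0] - means[1]).mean()

    observed = separation(truth)
    # under fold change 1 the domain split carries no more signal than
    # random label permutations of the same sizes
    rng = np.random.default_rng(0)
    null = [separation(rng.permutation(truth)) for _ in range(200)]
    assert observed < np.quantile(null, 0.99)


def test_marker_signal_supports_centroid_classification():
    spec = mvst.SyntheticSpec(seed=5)  # fold change 5, 50 markers/domain
    section, truth = mvst.generate_section(spec)
    counts = np.log1p(section.counts_dense())
    counts = counts / counts.std(axis=0).clip(1e-9)
    centroids = np.array([counts[truth == d].mean(axis=0) for d in range(3)])
    d2 = ((counts[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    acc = (d2.argmin(axis=1) == truth).mean()
    assert acc >= 0.95


@pytest.mark.parametrize("geometry", ["layered", "blocks", "voronoi"])
def test_geometries_cover_all_domains(geometry):
    spec = mvst.SyntheticSpec(n_rows=12, n_cols=12, n_genes=30,
                              n_marker_genes_per_domain=8, n_domains=3,
                              domain_geometry=geometry, seed=2)
    _, truth = mvst.generate_section(spec)
    assert set(truth) == {0, 1, 2}


# -------------------------------------------------------------------- dropout

def test_dropout_zero_is_identity(tiny_section):
    section, _ = tiny_section
    out = mvst.apply_dropout(section, 0.0, seed=1)
    np.testing.assert_array_equal(out.counts_dense(), section.counts_dense())


def test_dropout_rate_within_binomial_interval(tiny_section):
    section, _ = tiny_section
    base = section.counts_dense()
    nonzero = base > 0
    out = mvst.apply_dropout(section, 0.7, seed=3)
    zeroed = (out.counts_dense() == 0) & nonzero
    frac = zeroed.sum() / nonzero.sum()
    sigma = np.sqrt(0.7 * 0.3 / nonzero.sum())
    assert abs(frac - 0.7) < 3 * sigma  # ~99% interval


def test_dropout_reduces_nonzero_fraction_proportionally(tiny_section):
    section, _ = tiny_section
    base_nnz = (section.counts_dense() > 0).mean()
    out = mvst.apply_dropout(section, 0.4, seed=9)
    got = (out.counts_dense() > 0).mean()
    n = section.counts_dense().size
    assert abs(got - 0.6 * base_nnz) < 4 * np.sqrt(0.4 * 0.6 / n)


def test_dropout_masks_differ_across_seeds(tiny_section):
    section, _ = tiny_section
    a = mvst.apply_dropout(section, 0.7, seed=1).counts_dense()
    b = mvst.apply_dropout(section, 0.7, seed=2).counts_dense()
    assert not np.array_equal(a, b)


def test_dropout_cap_enforced(tiny_section):
    section, _ = tiny_section
    with pytest.raises(ValueError, match="cap"):
        mvst.apply_dropout(section, 0.71, seed=0)
    with pytest.raises(ValueError, match="non-negative"):
        mvst.apply_dropout(section, -0.1, seed=0)
    assert mvst.apply_dropout(section, DROPOUT_CAP, seed=0) is not None


# -------------------------------------------------------------- poisson noise

def test_poisson_noise_mean_matches_level_times_mean():
    counts = np.full((200, 500), 4, dtype=np.int64)
    section = mvst.SpatialSection(counts, np.random.default_rng(0).uniform(
        size=(200, 2)), [f"s{i}" for i in range(200)],
        [f"g{j}" for j in range(500)])
    out = mvst.apply_poisson_noise(section, 0.5, seed=0)
    added = out.counts_dense() - counts
    # lambda = 0.5 * 4 = 2; Monte-Carlo error at 1e5 entries ~ 0.0045
    assert abs(added.mean() - 2.0) < 0.02


def test_poisson_noise_additive_integer_contract(tiny_section):
    section, _ = tiny_section
    out = mvst.apply_poisson_noise(section, 0.3, seed=1)
    assert np.issubdtype(out.counts_dense().dtype, np.integer)
    assert np.all(out.counts_dense() >= section.counts_dense())


def test_poisson_noise_vanishes_at_zero_level(tiny_section):
    section, _ = tiny_section
    out = mvst.apply_poisson_noise(section, 0.0, seed=1)
    np.testing.assert_array_equal(out.counts_dense(), section.counts_dense())
    with pytest.raises(ValueError, match="non-negative"):
        mvst.apply_poisson_noise(section, -1.0, seed=0)


def test_poisson_per_gene_mode(tiny_section):
    section, _ = tiny_section
    out = mvst.apply_poisson_noise(section, 0.5, seed=1,
                                   noise_mean_mode="per_gene")
    added = out.counts_dense() - section.counts_dense()
    gene_means = section.counts_dense().mean(axis=0)
    heavy = gene_means > np.quantile(gene_means, 0.9)
    light = gene_means < np.quantile(gene_means, 0.1)
    assert added[:, heavy].mean() > added[:, light].mean()
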