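"""Clustering evaluation: the adjusted Rand index and partition utilities.

The ARI is computed from the pair-counting contingency form

    ARI = [ sum_ij C(n_ij,2) - sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) ]
          / [ (sum_i C(a_i,2) + sum_j C(b_j,2))/2
              - sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) ]

with n_ij the contingency counts, a_i/b_j the marginal class/cluster
sizes and n the number of points. Exact integer arithmetic is used
(Python ints), so the result is exact up to the final division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionPair", "contingency_table", "adjusted_rand_index"]

log = logging.getLogger(__name__)


@dataclass
class PartitionPair:
    """Two partitions of the same spots plus their contingency table."""

    truth: np.ndarray
    predicted: np.ndarray
    contingency: np.ndarray

    @property
    def n(self) -> int:
        return int(self.contingency.sum())


def contingency_table(truth, predicted) -> PartitionPair:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(predicted, return_inverse=True)
    u, v = ti.max() + 1, pi.max() + 1
    table = np.zeros((u, v), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return PartitionPair(truth, predicted, table)


def _comb2(x: np.ndarray) -> int:
    # sum of C(x,2) over entries, exact
    return int(sum(int(v) * (int(v) - 1) // 2 for v in x.ravel()))


def adjusted_rand_index(truth, predicted, mask_missing: bool = True) -> float:
    """Chance-corrected agreement between two labelings of the same spots.

    Parameters
    ----------
    truth, predicted
        Equal-length label vectors (any hashable label values).
    mask_missing
        When true, spots whose truth label is NaN or the string "NA" are
        excluded (with a logged count) before computing the index —
        manually annotated sections routinely leave some spots unlabeled.

    Returns
    -------
    float in [-1, 1]; 1 for identical partitions up to relabeling.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"label length mismatch: {truth.shape[0]} vs {predicted.shape[0]}"
        )
    if mask_missing:
        keep = np.ones(truth.shape[0], dtype=bool)
        if truth.dtype.kind == "f":
            keep &= ~np.isnan(truth.astype(float))
        elif truth.dtype.kind in "USO":
            keep &= ~np.isin(truth.astype(str), ("NA", "nan", ""))
        if not keep.all():
            log.info("ARI: excluding %d spots without truth annotation",
                     int((~keep).sum()))
            truth, predicted = truth[keep], predicted[keep]
    n = truth.shape[0]
    if n < 2:
        raise ValueError("ARI needs at least 2 spots")

    pair = contingency_table(truth, predicted)
    table = pair.contingency
    sum_ij = _comb2(table)
    sum_a = _comb2(table.sum(axis=1))
    sum_b = _comb2(table.sum(axis=0))
    total = n * (n - 1) // 2

    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    if denom == 0.0:
        # both partitions put everything in one cluster (or are otherwise
        # degenerate in the same way): identical partitions by convention
        return 1.0
    return float((sum_ij - expected) / denom)
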