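"""Per-sample normalizations: reads-per-million, quantile, rank.

Rank normalization replaces each sample's values by average-tied ranks
(1 = lowest, n = highest) rescaled by the rank sum n(n+1)/2 and multiplied
by 1e6, so every sample sums to one million and only within-sample order
survives — the property that makes models transfer across platforms.

RPM and rank act strictly per sample, so a matrix can be normalized in any
split without leakage. Quantile normalization needs a reference distribution:
``quantile_normalize`` builds it from the matrix itself, while
``QuantileReference`` freezes a training-set reference to apply to new samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix

SCALE = 1_000_000.0

METHODS = ("rpm", "quantile", "rank")


def rpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to sum to 1e6 (reads-per-million)."""
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total expression: "
            f"{', '.join(matrix.sample_ids[i] for i in zero)}"
        )
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        matrix.values / totals * SCALE,
    )


def rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each sample's values by average-tied ranks rescaled to sum 1e6."""
    n = matrix.n_genes
    ranks = rankdata(matrix.values, method="average", axis=0)  # ties -> mean rank
    rank_sum = n * (n + 1) / 2.0
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), ranks / rank_sum * SCALE
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization: rank-k value in every sample becomes the
    mean of rank-k values across samples; within-sample ties get the mean of
    the reference values over the tied span."""
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples for a reference")
    reference = np.sort(matrix.values, axis=0).mean(axis=1)
    return _map_to_reference(matrix, reference)


@dataclass
class QuantileReference:
    """A frozen reference distribution for normalizing held-out samples.

    Fit on training samples; ``transform`` maps each new sample's ranks onto
    the stored sorted reference vector, so test data never informs the reference.
    """

    reference: np.ndarray  # sorted, length n_genes
    gene_ids: list[str]

    @classmethod
    def fit(cls, matrix: ExpressionMatrix) -> "QuantileReference":
        if matrix.n_samples < 2:
            raise ValueError("quantile reference needs >= 2 samples")
        return cls(np.sort(matrix.values, axis=0).mean(axis=1), list(matrix.gene_ids))

    def transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        if list(matrix.gene_ids) != self.gene_ids:
            raise ValueError("gene universe differs from the fitted reference")
        return _map_to_reference(matrix, self.reference)


def _map_to_reference(matrix: ExpressionMatrix, reference: np.ndarray) -> ExpressionMatrix:
    # average-tied ranks in [1, n]; interpolate into the sorted reference so a
    # tied span receives the mean of the reference values it covers
    ranks = rankdata(matrix.values, method="average", axis=0)
    n = len(reference)
    grid = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(matrix.values, dtype=float)
    for j in range(matrix.n_samples):
        out[:, j] = _tied_reference_values(ranks[:, j], reference, grid)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


def _tied_reference_values(ranks: np.ndarray, reference: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # a value with average rank r over a tied span [lo, hi] gets
    # mean(reference[lo-1:hi]); untied ranks reduce to reference[r-1]
    out = np.empty_like(ranks)
    # group by rank value: identical average ranks share a tied span
    order = np.argsort(ranks, kind="stable")
    sorted_r = ranks[order]
    start = 0
    n = len(ranks)
    while start < n:
        stop = start
        while stop < n and sorted_r[stop] == sorted_r[start]:
            stop += 1
        span = stop - start  # number of tied values
        r = sorted_r[start]
        lo = int(round(r - (span - 1) / 2.0))
        hi = lo + span  # exclusive
        out[order[start:stop]] = reference[lo - 1 : hi - 1].mean()
        start = stop
    return out


def normalize(matrix: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Dispatch by method name (``rpm`` | ``quantile`` | ``rank``)."""
    method = method.lower()
    if method == "rpm":
        return rpm_normalize(matrix)
    if method == "quantile":
        return quantile_normalize(matrix)
    if method == "rank":
        return rank_normalize(matrix)
    raise ValueError(f"unknown normalization method {method!r}; expected one of {METHODS}")
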