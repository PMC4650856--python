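"""Expression preprocessing: log2 transform and quantile normalization.

Quantile normalization forces every sample (column) to share the same empirical
distribution — the per-rank mean across samples — so that between-array
intensity differences do not masquerade as biology. Tied values within a column
receive the mean of the reference values at the ranks they jointly occupy
(the standard "average rank" convention).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

__all__ = ["log2_transform", "quantile_normalize"]


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Element-wise log2(value + offset) on a raw-scale matrix.

    Raises ``ValueError`` if the matrix is already on the log2 scale, the
    offset is negative, or any shifted value is non-positive.
    """
    if m.scale != "raw":
        raise ValueError("log2_transform expects a raw-scale matrix")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = m.values + offset
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("non-positive values after offset; log2 undefined")
    return ExpressionMatrix(np.log2(shifted), scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the common per-rank mean distribution.

    After normalization every column holds the identical multiset of values
    (the mean of the sorted columns), assigned back in each column's own rank
    order; tied entries get the mean of the reference values at their ranks.
    Requires at least two samples.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = m.values.to_numpy(dtype=float)
    n_rows = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(n_rows, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average") - 1.0
        # average ranks land between integers; interpolate the reference there
        out[:, j] = np.interp(ranks, positions, reference)
    frame = m.values.copy()
    frame.loc[:, :] = out
    return ExpressionMatrix(frame, scale=m.scale)
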