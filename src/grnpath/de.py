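"""Differential expression by Student's t-test plus median-ratio fold change.

A feature is called differentially expressed between two groups when the
two-sided equal-variance t-test gives P < 0.01 (strict) and the linear-scale
median-ratio fold change is >= 2 or <= 0.5 (inclusive). On log2 data the
median-ratio fold change is 2^(median(A) - median(B)). No multiple-testing
correction enters the call; a Benjamini-Hochberg FDR column is emitted for
information only.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = ["median_ratio_fc", "t_test", "call_de"]


def median_ratio_fc(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Linear-scale ratio of group medians for log2 data: 2^(med(A) - med(B))."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold change needs non-empty groups")
    return float(2.0 ** (np.median(a) - np.median(b)))


def t_test(group_a: Sequence[float], group_b: Sequence[float], welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value (equal-variance Student by default).

    Degenerate case: zero variance in both groups yields p = 1 when the means
    are equal and p = 0 when they differ (the t statistic diverges).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs >= 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def call_de(
    matrix: ExpressionMatrix,
    metadata: pd.Series,
    contrast: tuple[Iterable[str], Iterable[str]],
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Call DE features between two class groups of a log2 matrix.

    ``contrast`` is a pair of class-label collections (A, B); pooling several
    labels on one side (e.g. PanNET + PDAC as "malignant") is just a
    multi-label group. Returns one row per feature with columns
    ``feature_id, p_value, fold_change, is_de, direction, fdr_bh``, where
    ``is_de`` iff p < p_threshold and FC >= fc_threshold or <= 1/fc_threshold.
    """
    if matrix.scale != "log2":
        raise ValueError("call_de expects a log2-scale matrix")
    labels_a, labels_b = set(contrast[0]), set(contrast[1])
    known = set(metadata.unique())
    unknown = (labels_a | labels_b) - known
    if unknown:
        raise ValueError(f"unknown class labels in contrast: {sorted(unknown)}")
    samples_a = [s for s in matrix.sample_ids if s in metadata.index and metadata[s] in labels_a]
    samples_b = [s for s in matrix.sample_ids if s in metadata.index and metadata[s] in labels_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both contrast groups need >= 2 samples")
    sub_a = matrix.values[samples_a].to_numpy(dtype=float)
    sub_b = matrix.values[samples_b].to_numpy(dtype=float)

    rows = []
    for i, fid in enumerate(matrix.feature_ids):
        p = t_test(sub_a[i], sub_b[i], welch=welch)
        fc = median_ratio_fc(sub_a[i], sub_b[i])
        passes_fc = fc >= fc_threshold or fc <= 1.0 / fc_threshold
        is_de = (p < p_threshold) and passes_fc
        if is_de:
            direction = "up" if fc >= fc_threshold else "down"
        else:
            direction = "none"
        rows.append({"feature_id": fid, "p_value": p, "fold_change": fc,
                     "is_de": is_de, "direction": direction})
    frame = pd.DataFrame(rows)
    frame["fdr_bh"] = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")[1]
    return frame
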