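"""KNN biomarker evaluation with cumulative ("one-dimensional") voting.

The classifier is a K-nearest-neighbor rule in Euclidean distance over the
log2 expression of a chosen gene set. Instead of committing to a single K,
the default voting scheme accumulates votes over every horizon K = 1..k_max:
class m scores

    Y_m = sum_{K=1}^{k_max} |{class-m samples among the K nearest neighbors}|

equivalently, the neighbor at rank r contributes k_max - r + 1 votes to its
class. At k_max = 1 this is exactly 1-NN. A plain fixed-K majority vote is
available as an alternative.

Gene sets are assessed by the jackknife (leave-one-out) test: each sample is
predicted from all remaining samples, and

    accuracy = 100 * (correct predictions) / (total predictions)   [percent].

``ChouKNNClassifier`` is a scikit-learn estimator (fit/predict, ``classes_``)
so it composes with sklearn model selection; the module functions wrap it for
the expression-matrix workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .matrix import ExpressionMatrix

__all__ = [
    "ChouKNNClassifier",
    "JackknifeResult",
    "chou_score",
    "knn_predict",
    "jackknife_accuracy",
    "per_gene_accuracy",
    "select_biomarker_set",
]


def chou_score(ranked_neighbor_labels: Sequence, k_max: int) -> dict:
    """Per-class cumulative-vote scores for a nearest-first ranked label list."""
    labels = list(ranked_neighbor_labels)
    if not labels:
        raise ValueError("empty neighbor list")
    if not (1 <= k_max <= len(labels)):
        raise ValueError(f"k_max must be in [1, {len(labels)}], got {k_max}")
    scores: dict = {}
    for rank, lab in enumerate(labels[:k_max], start=1):
        scores[lab] = scores.get(lab, 0) + (k_max - rank + 1)
    return scores


class ChouKNNClassifier(BaseEstimator, ClassifierMixin):
    """Euclidean KNN with cumulative voting over K = 1..k_max.

    Parameters
    ----------
    k_max : int, default=3
        Voting horizon of the cumulative scheme. Must be smaller than the
        number of training samples at fit time (the smallest class in a
        paper-scale leave-one-out run has 4-5 remaining members, hence the
        small default).
    voting : {"chou", "plain_majority"}, default="chou"
    k_plain : int, default=3
        Neighborhood size of the plain majority vote; must be odd.

    Tie-breaking is deterministic: neighbors at equal distance rank in
    training order (callers that need id-based ties sort their samples first),
    and tied class scores go to the class of the single nearest neighbor,
    then to the lexicographically smallest class.

    Attributes
    ----------
    classes_ : ndarray of unique class labels.
    X_, y_ : stored training data.
    n_features_in_ : int
    """

    def __init__(self, k_max: int = 3, voting: str = "chou", k_plain: int = 3):
        self.k_max = k_max
        self.voting = voting
        self.k_plain = k_plain

    def fit(self, X, y) -> "ChouKNNClassifier":
        X, y = check_X_y(X, y, dtype=float)
        if self.voting not in ("chou", "plain_majority"):
            raise ValueError("voting must be 'chou' or 'plain_majority'")
        k = self.k_max if self.voting == "chou" else self.k_plain
        if not (1 <= k <= X.shape[0] - (0 if self.voting == "chou" else 0)):
            raise ValueError(f"k={k} out of range for {X.shape[0]} training samples")
        if self.voting == "chou" and self.k_max >= X.shape[0] + 1:
            raise ValueError("k_max must not exceed the number of training samples")
        if self.voting == "plain_majority" and self.k_plain % 2 == 0:
            raise ValueError("k_plain must be odd")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain >= 2 classes")
        self.X_ = X
        self.y_ = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_one(self, x: np.ndarray):
        d = np.sqrt(((self.X_ - x) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")  # stable: distance ties keep training order
        ranked = self.y_[order]
        k = min(self.k_max if self.voting == "chou" else self.k_plain, ranked.size)
        if self.voting == "chou":
            scores = chou_score(ranked, k)
        else:
            scores = {}
            for lab in ranked[:k]:
                scores[lab] = scores.get(lab, 0) + 1
        top = max(scores.values())
        tied = sorted(lab for lab, s in scores.items() if s == top)
        if len(tied) > 1 and ranked[0] in tied:
            return ranked[0]
        return tied[0]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, classifier was fit with {self.n_features_in_}")
        return np.array([self._predict_one(row) for row in X])


@dataclass
class JackknifeResult:
    """Leave-one-out evaluation of one gene set."""

    gene_set: tuple[str, ...]
    per_sample: list[tuple[str, str, str]]  # (sample_id, true_label, predicted_label)
    accuracy_percent: float

    def recompute_accuracy(self) -> float:
        """Re-derive the accuracy from the per-sample records (exact)."""
        correct = sum(1 for _, truth, pred in self.per_sample if truth == pred)
        return 100.0 * correct / len(self.per_sample)


def _design(matrix: ExpressionMatrix, labels: Mapping[str, str],
            gene_set: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing}")
    # samples sorted by id so distance ties break on sample id deterministically
    samples = sorted(s for s in matrix.sample_ids if s in labels)
    X = matrix.values.loc[genes, samples].to_numpy(dtype=float).T
    y = np.array([labels[s] for s in samples])
    return X, y, samples


def knn_predict(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    gene_set: Sequence[str],
    query: Sequence[float],
    k_max: int = 3,
    voting: str = "chou",
    k_plain: int = 3,
):
    """Predict one query vector (values in gene_set order) from labeled samples."""
    X, y, _ = _design(matrix, labels, gene_set)
    clf = ChouKNNClassifier(k_max=k_max, voting=voting, k_plain=k_plain).fit(X, y)
    return clf.predict(np.asarray(query, dtype=float).reshape(1, -1))[0]


def jackknife_accuracy(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    gene_set: Sequence[str],
    k_max: int = 3,
    voting: str = "chou",
    k_plain: int = 3,
) -> JackknifeResult:
    """Leave-one-out accuracy of a gene set, in percent.

    Every class must have >= 2 samples so that each held-out sample still has
    same-class training neighbors available.
    """
    X, y, samples = _design(matrix, labels, gene_set)
    classes, counts = np.unique(y, return_counts=True)
    thin = [str(c) for c, n in zip(classes, counts) if n < 2]
    if thin:
        raise ValueError(f"classes with a single sample cannot be jackknifed: {thin}")
    per_sample: list[tuple[str, str, str]] = []
    n = len(samples)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        kmax_eff = min(k_max, n - 1)
        clf = ChouKNNClassifier(k_max=kmax_eff, voting=voting,
                                k_plain=min(k_plain, n - 1 if (n - 1) % 2 else n - 2))
        clf.fit(X[mask], y[mask])
        pred = clf.predict(X[i:i + 1])[0]
        per_sample.append((samples[i], str(y[i]), str(pred)))
        mask[i] = True
    correct = sum(1 for _, truth, pred in per_sample if truth == pred)
    return JackknifeResult(tuple(gene_set), per_sample, 100.0 * correct / n)


def per_gene_accuracy(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    candidate_genes: Sequence[str],
    k_max: int = 3,
    voting: str = "chou",
    k_plain: int = 3,
) -> pd.DataFrame:
    """Jackknife accuracy of every singleton gene set, sorted descending.

    Ties in accuracy are ordered by feature id for determinism.
    """
    rows = []
    for gene in candidate_genes:
        res = jackknife_accuracy(matrix, labels, [gene], k_max=k_max,
                                 voting=voting, k_plain=k_plain)
        rows.append({"feature_id": gene, "accuracy_percent": res.accuracy_percent})
    frame = pd.DataFrame(rows, columns=["feature_id", "accuracy_percent"])
    return frame.sort_values(
        ["accuracy_percent", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)


def select_biomarker_set(
    per_gene_table: pd.DataFrame,
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    k_max: int = 3,
    voting: str = "chou",
    k_plain: int = 3,
    strategy: str = "greedy",
    accuracy_threshold: float = 100.0,
) -> tuple[list[str], JackknifeResult]:
    """Assemble a discriminating gene set from the per-gene accuracy ranking.

    ``greedy`` (default): forward selection in descending per-gene-accuracy
    order, adding a gene whenever it strictly increases the joint jackknife
    accuracy, stopping at 100 % or exhaustion. ``threshold``: keep every gene
    whose singleton accuracy is >= ``accuracy_threshold``.
    """
    if strategy not in ("greedy", "threshold"):
        raise ValueError("strategy must be 'greedy' or 'threshold'")
    ranked = per_gene_table["feature_id"].tolist()
    if strategy == "threshold":
        chosen = per_gene_table.loc[
            per_gene_table["accuracy_percent"] >= accuracy_threshold, "feature_id"].tolist()
        if not chosen:
            chosen = ranked[:1]
        return chosen, jackknife_accuracy(matrix, labels, chosen, k_max=k_max,
                                          voting=voting, k_plain=k_plain)
    chosen = [ranked[0]]
    best = jackknife_accuracy(matrix, labels, chosen, k_max=k_max,
                              voting=voting, k_plain=k_plain)
    for gene in ranked[1:]:
        if best.accuracy_percent >= 100.0:
            break
        trial = jackknife_accuracy(matrix, labels, chosen + [gene], k_max=k_max,
                                   voting=voting, k_plain=k_plain)
        if trial.accuracy_percent > best.accuracy_percent:
            chosen.append(gene)
            best = trial
    return chosen, best


def pool_labels(metadata: pd.Series, pools: Mapping[str, Iterable[str]],
                keep: Iterable[str] | None = None) -> dict[str, str]:
    """Relabel samples, pooling classes (e.g. PanNET + PDAC -> "malignant").

    Samples whose class is in a pool get the pool name; samples in ``keep``
    classes keep their label; all others are dropped.
    """
    inverse = {}
    for pool_name, members in pools.items():
        for m in members:
            inverse[m] = pool_name
    keep_set = set(keep) if keep is not None else set()
    out: dict[str, str] = {}
    for sample, label in metadata.items():
        if label in inverse:
            out[sample] = inverse[label]
        elif label in keep_set:
            out[sample] = label
    return out
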