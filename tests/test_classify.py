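"""Cumulative-vote KNN, jackknife evaluation and biomarker-set selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from grnpath.classify import (ChouKNNClassifier, chou_score, jackknife_accuracy,
                              knn_predict, per_gene_accuracy, pool_labels,
                              select_biomarker_set)
from grnpath.matrix import ExpressionMatrix


def _matrix(array, samples=None, features=None):
    array = np.asarray(array, float)
    features = features or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{i:02d}" for i in range(array.shape[1])]
    return ExpressionMatrix(pd.DataFrame(array, index=features, columns=samples))


class TestChouScore:
    def test_cumulative_votes_direct_evaluation(self):
        # ranks contribute k_max - r + 1 votes: (A,A,B) at k_max=3 -> A:3+2, B:1
        assert chou_score(["A", "A", "B"], 3) == {"A": 5, "B": 1}

    def test_single_class_closed_form(self):
        k = 5
        assert chou_score(["A"] * k, k) == {"A": k * (k + 1) // 2}

    def test_nearest_breaks_symmetry(self):
        assert chou_score(["A", "B"], 2) == {"A": 2, "B": 1}

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            chou_score([], 1)


class TestChouKNNClassifier:
    def test_kmax_one_equals_sklearn_1nn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(12, 3))
            y = rng.choice(["a", "b", "c"], size=12)
            if len(set(y)) < 2:
                continue
            Q = rng.normal(size=(6, 3))
            ours = ChouKNNClassifier(k_max=1).fit(X, y).predict(Q)
            ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(Q)
            assert list(ours) == list(ref)

    def test_query_equal_to_training_sample(self):
        X = np.array([[0.0], [5.0], [9.0]])
        y = np.array(["a", "b", "b"])
        clf = ChouKNNClassifier(k_max=1).fit(X, y)
        assert clf.predict([[5.0]])[0] == "b"

    def test_two_cluster_separation(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 0.1, (10, 1)), rng.normal(10, 0.1, (10, 1))])
        y = np.array(["lo"] * 10 + ["hi"] * 10)
        clf = ChouKNNClassifier(k_max=3).fit(X, y)
        assert clf.predict([[0.2]])[0] == "lo"
        assert clf.predict([[9.7]])[0] == "hi"

    def test_equidistant_neighbors_rank_in_training_order(self):
        # both neighbors at distance 1; stable sort ranks index 0 first
        X = np.array([[1.0], [-1.0], [30.0], [-30.0]])
        y = np.array(["a", "b", "a", "b"])
        clf = ChouKNNClassifier(k_max=2).fit(X, y)
        assert clf.predict([[0.0]])[0] == "a"

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        y = rng.choice(["a", "b"], size=10)
        Q = rng.normal(size=(5, 4))
        base = ChouKNNClassifier(k_max=3).fit(X, y).predict(Q)
        shifted = ChouKNNClassifier(k_max=3).fit(X + 7.5, y).predict(Q + 7.5)
        assert list(base) == list(shifted)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            ChouKNNClassifier(k_max=1).fit(np.zeros((3, 1)), ["a", "a", "a"])

    def test_plain_majority_requires_odd_k(self):
        with pytest.raises(ValueError, match="odd"):
            ChouKNNClassifier(voting="plain_majority", k_plain=2).fit(
                np.zeros((4, 1)) + np.arange(4)[:, None], ["a", "a", "b", "b"])

    def test_sklearn_param_interface(self):
        clf = ChouKNNClassifier(k_max=5)
        assert clf.get_params()["k_max"] == 5
        clf.set_params(k_max=2)
        assert clf.k_max == 2


class TestJackknife:
    def test_accuracy_rederivable_from_per_sample_records(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, (5, 12)))
        labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(m.sample_ids)}
        res = jackknife_accuracy(m, labels, ["g0", "g1"])
        assert res.accuracy_percent == res.recompute_accuracy()  # exact

    def test_perfect_separation_gives_100(self):
        arr = np.concatenate([np.full((1, 6), 0.0), ], axis=0)
        arr = np.concatenate([np.zeros((1, 6)), ], axis=1)
        vals = np.concatenate([np.full(6, 0.0), np.full(6, 10.0)])[None, :]
        vals = vals + np.random.default_rng(4).normal(0, 0.05, vals.shape)
        m = _matrix(vals)
        labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(m.sample_ids)}
        assert jackknife_accuracy(m, labels, ["g0"]).accuracy_percent == 100.0

    def test_singleton_class_errors_naming_class(self):
        m = _matrix(np.random.default_rng(5).normal(size=(2, 5)))
        labels = dict(zip(m.sample_ids, ["A", "A", "A", "A", "B"]))
        with pytest.raises(ValueError, match="B"):
            jackknife_accuracy(m, labels, ["g0"])

    def test_constant_gene_matches_brute_force_tie_baseline(self):
        # all distances zero: every prediction falls to the deterministic
        # tie-break; replicate it directly from the ranked training labels
        m = _matrix(np.full((1, 8), 5.0))
        sids = m.sample_ids
        labels = {s: ("A" if i < 5 else "B") for i, s in enumerate(sids)}
        res = jackknife_accuracy(m, labels, ["g0"], k_max=3)
        for sample, truth, pred in res.per_sample:
            train = [s for s in sids if s != sample]
            ranked = [labels[s] for s in train]  # id order = training order
            scores = chou_score(ranked, 3)
            top = max(scores.values())
            tied = sorted(c for c, v in scores.items() if v == top)
            expected = ranked[0] if len(tied) > 1 and ranked[0] in tied else tied[0]
            assert pred == expected

    def test_knn_predict_wrapper(self):
        vals = np.concatenate([np.full(4, 0.0), np.full(4, 10.0)])[None, :]
        m = _matrix(vals)
        labels = {s: ("lo" if i < 4 else "hi") for i, s in enumerate(m.sample_ids)}
        assert knn_predict(m, labels, ["g0"], [9.8], k_max=3) == "hi"


class TestSelection:
    def _planted(self, rng, n_markers=3, n_noise=10, n_per_class=7):
        n = 2 * n_per_class
        vals = rng.normal(8, 0.5, (n_markers + n_noise, n))
        vals[:n_markers, :n_per_class] += 4.0
        m = _matrix(vals)
        labels = {s: ("A" if i < n_per_class else "B")
                  for i, s in enumerate(m.sample_ids)}
        return m, labels

    def test_per_gene_table_shape_and_sorting(self):
        rng = np.random.default_rng(6)
        m, labels = self._planted(rng)
        table = per_gene_accuracy(m, labels, list(m.feature_ids))
        assert len(table) == len(m.feature_ids)
        accs = table["accuracy_percent"].to_numpy()
        assert (np.diff(accs) <= 0).all()

    def test_planted_markers_rank_top(self):
        rng = np.random.default_rng(7)
        m, labels = self._planted(rng, n_markers=3)
        table = per_gene_accuracy(m, labels, list(m.feature_ids))
        assert set(table.head(3)["feature_id"]) == {"g0", "g1", "g2"}

    def test_greedy_reaches_100_with_perfect_markers(self):
        rng = np.random.default_rng(8)
        m, labels = self._planted(rng)
        table = per_gene_accuracy(m, labels, list(m.feature_ids))
        genes, res = select_biomarker_set(table, m, labels, strategy="greedy")
        assert res.accuracy_percent == 100.0
        assert set(genes) <= set(m.feature_ids)

    def test_threshold_strategy_is_definitional(self):
        rng = np.random.default_rng(9)
        m, labels = self._planted(rng)
        table = per_gene_accuracy(m, labels, list(m.feature_ids))
        genes, _ = select_biomarker_set(table, m, labels, strategy="threshold",
                                        accuracy_threshold=100.0)
        perfect = set(table.loc[table["accuracy_percent"] >= 100.0, "feature_id"])
        assert set(genes) == perfect

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(10)
        m, labels = self._planted(rng)
        res1 = jackknife_accuracy(m, labels, ["g0", "g1", "g2"])
        res2 = jackknife_accuracy(m, labels, ["g2", "g0", "g1"])
        assert res1.accuracy_percent == res2.accuracy_percent
        assert [p[2] for p in res1.per_sample] == [p[2] for p in res2.per_sample]


class TestPoolLabels:
    def test_pooling_and_keep(self):
        meta = pd.Series({"s1": "SPN", "s2": "PanNET", "s3": "PDAC", "s4": "normal"})
        labels = pool_labels(meta, {"malignant": ["PanNET", "PDAC"]}, keep=["SPN"])
        assert labels == {"s1": "SPN", "s2": "malignant", "s3": "malignant"}
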