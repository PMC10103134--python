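"""Random forest: entropy splits, tree growth, voting, OOB, serialization."""

import json
import math

import numpy as np
import pytest

from gagir.forest import (
    ForestConfig,
    ForestModel,
    UndefinedOOBError,
    best_split,
    entropy,
    grow_tree,
    oob_error,
    predict,
    train_forest,
)


def brute_force_best_split(X, y, candidates):
    """Exhaustive oracle: all candidate features × all midpoints.

    Pure-Python reimplementation with the same tie-break contract
    (lower feature index, then lower threshold)."""

    def H(labels):
        n = len(labels)
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / n
            h -= p * math.log2(p)
        return h

    rows = [list(r) for r in X]
    labels = list(y)
    parent = H(labels)
    best = None
    for f in sorted(candidates):
        vals = sorted(set(r[f] for r in rows))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [l for r, l in zip(rows, labels) if r[f] <= thr]
            right = [l for r, l in zip(rows, labels) if r[f] > thr]
            gain = parent - (len(left) * H(left) + len(right) * H(right)) / len(labels)
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (f, thr, gain)
    return best


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 5, "B": 5}, 1.0),
            ({"A": 8, "B": 0}, 0.0),
            ({"A": 3, "B": 1}, -0.75 * math.log2(0.75) - 0.25 * math.log2(0.25)),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            entropy({"A": 0, "B": 0})

    def test_bounds_and_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            c = rng.integers(0, 20, size=2)
            if c.sum() == 0:
                continue
            h = entropy(c)
            assert 0 <= h <= 1.0 + 1e-12
            if 0 in c:
                assert h == 0.0


class TestBestSplit:
    def test_perfect_single_feature(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 0, 1, 1])
        assert best_split(X, y, [0]) == (0, pytest.approx(0.5), pytest.approx(1.0))

    def test_pure_labels_no_split(self):
        X = np.array([[0.1], [0.5], [0.9]])
        assert best_split(X, np.array([1, 1, 1]), [0]) is None

    def test_tie_breaks_to_lower_feature_index(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, gain = best_split(X, y, [0, 1])
        assert f == 0 and thr == pytest.approx(0.5) and gain == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self):
        """Randomized equivalence against the brute-force oracle
        (≤ 5 features × ≤ 12 samples)."""
        rng = np.random.default_rng(12345)
        for trial in range(300):
            n = rng.integers(2, 13)
            k = rng.integers(1, 6)
            # low-cardinality values provoke duplicates and ties
            X = np.round(rng.random((n, k)) * rng.integers(2, 6), 1)
            y = rng.integers(0, 2, n)
            cand = sorted(rng.choice(k, size=rng.integers(1, k + 1), replace=False))
            expected = brute_force_best_split(X, y, cand)
            got = best_split(X, y, cand)
            if expected is None:
                assert got is None
            else:
                assert got[0] == expected[0]
                assert got[1] == pytest.approx(expected[1])
                assert got[2] == pytest.approx(expected[2], abs=1e-12)


class TestGrowTree:
    def test_single_class_yields_single_leaf(self):
        X = np.array([[0.1], [0.2], [0.3]])
        model = grow_tree(X, np.array([1, 1, 1]), seed=0)
        root = model.tree_root(0)
        assert root.is_leaf

    def test_separable_rows_fit_perfectly(self, separable_xy):
        X, y = separable_xy
        model = grow_tree(X, y, seed=3)
        preds = [model.predict_one(row).label for row in X]
        assert preds == list(y)

    def test_deterministic_under_seed(self, separable_xy):
        X, y = separable_xy
        a = grow_tree(X, y, seed=7)
        b = grow_tree(X, y, seed=7)
        assert a.to_json() == b.to_json()


class TestTrainForest:
    def test_deterministic_predictions(self, separable_xy):
        X, y = separable_xy
        cfg = ForestConfig(n_trees=30, seed=9)
        m1, m2 = train_forest(X, y, cfg), train_forest(X, y, cfg)
        assert m1.to_json() == m2.to_json()
        assert [p.label for p in m1.predict_many(X)] == [p.label for p in m2.predict_many(X)]

    def test_bootstrap_distinct_fraction(self):
        """E[#distinct]/n for bootstrap of n=16 is 1-(1-1/16)^16 ≈ 0.644."""
        n = 16
        X = np.zeros((n, 1))
        y = np.arange(n) % 2
        model = train_forest(X, y, ForestConfig(n_trees=500, seed=0))
        fracs = [
            np.unique(model.bootstrap_indices[t]).size / n for t in range(model.n_trees)
        ]
        assert np.mean(fracs) == pytest.approx(1 - (1 - 1 / n) ** n, abs=0.02)

    def test_bootstrap_and_oob_are_complements(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=10, seed=1))
        for t in range(model.n_trees):
            inbag = set(model.bootstrap_indices[t].tolist())
            oob = set(model.oob_indices(t).tolist())
            assert inbag | oob == set(range(X.shape[0]))
            assert inbag & oob == set()

    def test_single_class_degenerates_with_warning(self):
        X = np.random.default_rng(0).random((6, 3))
        with pytest.warns(UserWarning):
            model = train_forest(X, np.ones(6, dtype=int), ForestConfig(n_trees=5, seed=0))
        pred = model.predict_one(X[0])
        assert pred.label == 1 and pred.confidence == 1.0

    def test_matches_sklearn_on_separable_data(self, separable_xy):
        """Independent cross-check: sklearn's entropy forest also reaches
        100% training accuracy on the same separable problem."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        X, y = separable_xy
        ours = train_forest(X, y, ForestConfig(n_trees=50, seed=2))
        ref = sklearn.RandomForestClassifier(
            n_estimators=50, criterion="entropy", random_state=2
        ).fit(X, y)
        assert [p.label for p in ours.predict_many(X)] == list(y)
        assert list(ref.predict(X)) == list(y)


class TestPredict:
    def test_confidence_is_vote_fraction(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=100, seed=5))
        for row in X:
            p = model.predict_one(row)
            votes = model.votes(row.reshape(1, -1))[0]
            n1 = votes.sum()
            expected = max(n1, 100 - n1) / 100
            assert p.confidence == pytest.approx(expected)
            assert p.confidence >= 0.5

    def test_tie_breaks_to_negative_class(self):
        # hand-built 2-tree model voting 1 vs 0
        X = np.array([[0.0], [1.0]])
        y = np.array([False, True])
        model = train_forest(X, y, ForestConfig(n_trees=2, seed=0))
        model.feat[:] = -1  # force both trees to leaves with opposing counts
        model.cnt0[0, 0], model.cnt1[0, 0] = 1, 0
        model.cnt0[1, 0], model.cnt1[1, 0] = 0, 1
        p = model.predict_one([0.5])
        assert p.label is False and p.confidence == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=3, seed=0))
        with pytest.raises(ValueError):
            predict(model, np.zeros(X.shape[1] + 1))


class TestOOB:
    def test_zero_for_separable_data(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=200, seed=0))
        assert oob_error(model, X, y) == 0.0

    def test_near_half_for_random_labels(self):
        rng = np.random.default_rng(7)
        X = rng.random((40, 5))
        y = rng.integers(0, 2, 40)  # labels independent of features
        model = train_forest(X, y, ForestConfig(n_trees=100, seed=7))
        assert oob_error(model, X, y) == pytest.approx(0.5, abs=0.15)

    def test_inbag_sample_excluded_with_one_tree(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = train_forest(X, y, ForestConfig(n_trees=1, seed=4))
        inbag = set(model.bootstrap_indices[0].tolist())
        if len(inbag) == 4:
            with pytest.raises(UndefinedOOBError):
                oob_error(model, X, y)
        else:
            oob_error(model, X, y)  # only OOB rows contribute


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=20, seed=6))
        restored = ForestModel.from_json(model.to_json())
        assert restored.to_json() == model.to_json()
        assert [p.label for p in restored.predict_many(X)] == [
            p.label for p in model.predict_many(X)
        ]
        assert restored.digest() == model.digest()

    def test_format_is_versioned(self, separable_xy):
        X, y = separable_xy
        model = train_forest(X, y, ForestConfig(n_trees=2, seed=0))
        d = json.loads(model.to_json())
        assert d["format_version"] == 1
        d["format_version"] = 99
        with pytest.raises(ValueError):
            ForestModel.from_dict(d)
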