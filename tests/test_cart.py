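"""CART growth, splitting, prediction, cross-validation, importance."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropclass.cart import (
    TreeParams,
    best_split,
    cross_validate,
    gini,
    grow_tree,
    predict,
    predict_matrix,
    resubstitution_risk,
    variable_importance,
)
from cropclass.features import MatrixData


def oracle_best_split(X, y, feature_names, min_child):
    """Exhaustive enumeration with exact Fraction arithmetic.

    Maximizes sum over children of sum_i c_i^2 / n_child (equivalent to
    maximizing Gini improvement at fixed parent); first feature then
    smallest threshold wins ties; returns None when the best equals the
    parent score (zero improvement).
    """
    n = len(y)
    classes = sorted(set(y))
    parent = Fraction(sum(list(y).count(c) ** 2 for c in classes), n)
    best = None
    for j, name in enumerate(feature_names):
        for thr in sorted({(a + b) / 2 for a, b in
                           zip(sorted(set(X[:, j]))[:-1], sorted(set(X[:, j]))[1:])}):
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            if len(left) < min_child or len(right) < min_child:
                continue
            score = (
                Fraction(sum(left.count(c) ** 2 for c in classes), len(left))
                + Fraction(sum(right.count(c) ** 2 for c in classes), len(right))
            )
            if best is None or score > best[0]:
                best = (score, name, thr)
    if best is None or best[0] == parent:
        return None
    return best[1], best[2]


def _node_frame(X, y, names):
    frame = pd.DataFrame(X, columns=names)
    frame["label"] = y
    return frame


def _matrix(X, y, names):
    frame = _node_frame(X, y, names)
    frame.index = pd.Index([f"p{i}" for i in range(len(frame))], name="parcel_id")
    return MatrixData(frame)


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini((8, 0, 0)) == 0.0

    def test_two_class_symmetric_maximum(self):
        assert gini((5, 5)) == pytest.approx(0.5)

    def test_three_class_direct_evaluation(self):
        # p = (0.5, 0.25, 0.25) -> 0.5*0.5 + 0.25*0.75 + 0.25*0.75
        assert gini((2, 1, 1)) == pytest.approx(0.625)

    def test_accepts_count_mapping(self):
        assert gini({"A": 2, "B": 1, "C": 1}) == pytest.approx(0.625)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=6).filter(sum))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_purity(self, counts):
        k = sum(1 for c in counts if c > 0)
        g = gini(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / max(k, 1) + 1e-12
        assert (g == 0.0) == (k == 1)


class TestBestSplit:
    def test_four_point_example(self):
        frame = _node_frame([[1.0], [2.0], [3.0], [4.0]], list("AABB"), ["T1NDVI"])
        split = best_split(frame, ["T1NDVI"], TreeParams(min_parent=2, min_child=1))
        assert split.variable == "T1NDVI"
        assert split.threshold == pytest.approx(2.5)
        assert split.improvement == pytest.approx(0.5)

    def test_pure_node_has_no_split(self):
        frame = _node_frame([[1.0], [2.0], [3.0]], list("AAA"), ["T1NDVI"])
        assert best_split(frame, ["T1NDVI"], TreeParams(min_parent=2, min_child=1)) is None

    def test_below_min_parent_rejected(self):
        frame = _node_frame([[1.0], [2.0]], list("AB"), ["T1NDVI"])
        with pytest.raises(ValueError, match="min_parent"):
            best_split(frame, ["T1NDVI"], TreeParams(min_parent=8, min_child=1))

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        names = ["T1NDVI", "T1Stu", "T2NDVI"]
        params = TreeParams(min_parent=2, min_child=1)
        for trial in range(200):
            n = int(rng.integers(4, 31))
            p = int(rng.integers(1, 4))
            # small integer grids force exact improvement ties
            X = rng.integers(0, 5, (n, p)).astype(float)
            y = [["A", "B", "C"][i] for i in rng.integers(0, 3, n)]
            min_child = int(rng.integers(1, 4))
            params = TreeParams(min_parent=2, min_child=min_child)
            got = best_split(_node_frame(X, y, names[:p]), names[:p], params)
            want = oracle_best_split(X, np.array(y), names[:p], min_child)
            if want is None:
                assert got is None, f"trial {trial}"
            else:
                assert (got.variable, got.threshold) == want, f"trial {trial}"

    def test_agrees_with_sklearn_on_tie_free_data(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        X = rng.normal(size=(60, 3))
        y = (X[:, 1] + 0.2 * rng.normal(size=60) > 0).astype(int)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=1, random_state=0
        ).fit(X, y)
        names = ["T1Blue", "T1Gree", "T1Red"]
        split = best_split(
            _node_frame(X, [str(v) for v in y], names),
            names,
            TreeParams(min_parent=2, min_child=1),
        )
        assert names.index(split.variable) == clf.tree_.feature[0]
        # sklearn casts features to float32 internally, so thresholds match
        # only to single precision
        assert split.threshold == pytest.approx(clf.tree_.threshold[0], rel=1e-6)


class TestGrowPredict:
    def test_linearly_separable_two_class_is_depth_one(self, rng):
        X = np.concatenate([rng.uniform(0, 0.3, 20), rng.uniform(0.7, 1.0, 20)])
        y = ["A"] * 20 + ["B"] * 20
        m = _matrix(X[:, None], y, ["T1NDVI"])
        tree = grow_tree(m, TreeParams())
        assert tree.depth == 1
        assert resubstitution_risk(tree, m).risk == 0.0

    def test_max_depth_zero_predicts_majority(self):
        m = _matrix([[0.1], [0.2], [0.3]], ["A", "A", "B"], ["T1NDVI"])
        tree = grow_tree(m, TreeParams(max_depth=0, min_parent=2, min_child=1))
        assert tree.root.is_leaf
        assert predict(tree, {"T1NDVI": 99.0}) == ("A", pytest.approx(2 / 3))

    def test_single_class_input_gives_depth_zero_tree(self):
        m = _matrix([[0.1], [0.2]], ["A", "A"], ["T1NDVI"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1))
        assert tree.root.is_leaf and tree.root.terminal_class == "A"

    def test_value_at_threshold_goes_left(self):
        m = _matrix([[1.0], [2.0], [3.0], [4.0]], list("AABB"), ["T1NDVI"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1))
        thr = tree.root.split.threshold
        assert predict(tree, {"T1NDVI": thr})[0] == "A"

    def test_missing_variable_is_named(self):
        m = _matrix([[1.0], [2.0], [3.0], [4.0]], list("AABB"), ["T1NDVI"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1))
        with pytest.raises(KeyError, match="T1NDVI"):
            predict(tree, {"T2NDVI": 1.0})

    def test_training_rows_reach_their_growth_leaf(self, default_study):
        train, _ = default_study
        tree = grow_tree(train, TreeParams(max_depth=12, seed=1))
        bulk = predict_matrix(tree, train)
        for (pid, row), want in zip(train.features().iterrows(), bulk):
            assert predict(tree, dict(row))[0] == want

    def test_min_child_and_nonnegative_improvement(self, default_study):
        train, _ = default_study
        tree = grow_tree(train, TreeParams(max_depth=12, seed=1))
        for node in tree.nodes():
            if node.split is not None:
                assert node.split.improvement >= 0
                assert node.left.size >= tree.params.min_child
                assert node.right.size >= tree.params.min_child
                assert node.left.size + node.right.size == node.size
            assert sum(node.class_counts.values()) == node.size

    def test_resubstitution_risk_nonincreasing_in_depth(self, default_study):
        train, _ = default_study
        risks = [
            resubstitution_risk(grow_tree(train, TreeParams(max_depth=d)), train).risk
            for d in (0, 1, 3, 5, 8, 12)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(risks, risks[1:]))

    def test_synthetic_phenology_recovery(self, default_study):
        train, _ = default_study
        tree = grow_tree(train, TreeParams(max_depth=12, seed=1))
        assert 1 - resubstitution_risk(tree, train).risk >= 0.95

    def test_json_round_trip(self, tmp_path, default_study):
        from cropclass.cart import Tree

        train, _ = default_study
        tree = grow_tree(train, TreeParams(seed=1))
        path = tmp_path / "tree.json"
        tree.save(path)
        back = Tree.load(path)
        assert back.to_dict() == tree.to_dict()
        assert list(predict_matrix(back, train)) == list(predict_matrix(tree, train))


class TestCrossValidation:
    def test_se_closed_form(self):
        # risk 0.4 over 156 cases -> binomial SE prints as 0.04
        se = np.sqrt(0.4 * 0.6 / 156)
        assert se == pytest.approx(0.039, abs=5e-4)

    def test_separable_data_has_near_zero_risk(self, rng):
        X = np.concatenate([rng.uniform(0, 0.3, 30), rng.uniform(0.7, 1.0, 30)])
        m = _matrix(X[:, None], ["A"] * 30 + ["B"] * 30, ["T1NDVI"])
        est = cross_validate(m, TreeParams(seed=0))
        assert est.risk <= 0.05
        assert est.method == "cross_validation"
        assert est.se == pytest.approx(np.sqrt(est.risk * (1 - est.risk) / 60))

    def test_shuffled_labels_approach_chance(self, rng):
        # labels independent of features: held-out risk ~ 1 - 1/k
        k = 3
        X = rng.normal(size=(120, 2))
        y = [["A", "B", "C"][i] for i in rng.integers(0, k, 120)]
        m = _matrix(X, y, ["T1NDVI", "T1Stu"])
        est = cross_validate(m, TreeParams(min_parent=8, min_child=4, seed=0))
        assert est.risk == pytest.approx(1 - 1 / k, abs=0.15)

    def test_small_class_reduces_folds_with_warning(self, rng):
        X = rng.normal(size=(20, 1))
        y = ["A"] * 17 + ["B"] * 3
        m = _matrix(X, y, ["T1NDVI"])
        with pytest.warns(UserWarning, match="folds"):
            cross_validate(m, TreeParams(cv_folds=10, seed=0))

    def test_too_few_rows_rejected(self):
        m = _matrix([[1.0]], ["A"], ["T1NDVI"])
        with pytest.raises(ValueError):
            cross_validate(m, TreeParams())


class TestImportance:
    def test_depth_one_tree_single_variable_at_100(self):
        m = _matrix([[1.0], [2.0], [3.0], [4.0]], list("AABB"), ["T1NDVI"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1))
        assert variable_importance(tree) == [("T1NDVI", 100.0)]

    def test_splitless_tree_is_empty(self):
        m = _matrix([[1.0], [2.0]], ["A", "A"], ["T1NDVI"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1))
        assert variable_importance(tree) == []

    def test_symmetric_two_split_tree_both_100(self):
        # XOR-free symmetric layout: two variables each cleanly split one half
        X = [[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 2
        y = ["A", "A", "B", "C"] * 2
        m = _matrix(X, y, ["T1NDVI", "T1Stu"])
        tree = grow_tree(m, TreeParams(min_parent=2, min_child=1, max_depth=3))
        imp = dict(variable_importance(tree))
        assert set(imp) == {"T1NDVI", "T1Stu"}

    def test_normalization_properties_on_grown_trees(self, default_study):
        train, _ = default_study
        for depth in (3, 5, 12):
            imp = variable_importance(grow_tree(train, TreeParams(max_depth=depth)))
            values = [v for _, v in imp]
            assert values and max(values) == pytest.approx(100.0)
            assert all(0 < v <= 100.0 for v in values)
            assert values == sorted(values, reverse=True)
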