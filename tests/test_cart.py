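"""Unit and property tests for the tree mathematics.

The impurity functionals are checked against independent direct-summation
oracles, the split search against exhaustive enumeration and against
scikit-learn's stump search, and tree growth against hand-constructed
datasets (1-D separable, XOR) whose optimal structure is known.
"""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decontree.cart import (
    CostMatrix,
    TreeConfig,
    best_split,
    entropy,
    fit_regression_tree,
    fit_tree,
    gini,
    gini_from_counts,
    information_gain,
    leaf_posteriors,
    predict_regression_tree,
    predict_tree,
    tree_from_json,
    tree_importance,
    tree_to_json,
)

# ---------------------------------------------------------------------------
# independent oracles: direct summation, no shared code with the implementation


def entropy_oracle(counts):
    n = sum(counts)
    if n == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / n) * math.log2(c / n)
    return h


def gini_oracle(props):
    return sum(p * (1 - p) for p in props)


def ig_oracle(parent, children):
    n = sum(parent)
    if n == 0:
        return 0.0
    return entropy_oracle(parent) - sum(
        (sum(ch) / n) * entropy_oracle(ch) for ch in children
    )


def brute_force_split(X, y, candidates, min_leaf=1):
    """Enumerate every predictor x midpoint; n-weighted child Gini."""
    n = len(y)
    best = None
    for col in sorted(candidates):
        vals = sorted(set(X[:, col]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            mask = X[:, col] <= thr
            nl, nr = mask.sum(), (~mask).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            score = 0.0
            for m, k in ((mask, nl), (~mask, nr)):
                counts = np.bincount(y[m], minlength=2)
                score += (k / n) * gini_oracle(counts / k)
            if best is None or score < best[0] - 1e-12:
                best = (score, col, thr)
    parent = np.bincount(y, minlength=2)
    if best is None or gini_oracle(parent / n) - best[0] <= 1e-12:
        return None
    return best


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"target": 5, "contaminant": 5}, 1.0),
        ({"target": 10, "contaminant": 0}, 0.0),
        ({"target": 3, "contaminant": 1}, 0.811278),
        ([0, 0], 0.0),
    ],
)
def test_entropy_examples(counts, expected):
    assert entropy(counts) == pytest.approx(expected, abs=1e-6)


def test_entropy_rejects_negative_counts():
    with pytest.raises(ValueError):
        entropy([-1, 3])


@pytest.mark.parametrize(
    "parent, children, expected",
    [
        ([2, 2], [[2, 0], [0, 2]], 1.0),
        ([4, 4], [[2, 2], [2, 2]], 0.0),
        ([3, 1], [[2, 0], [1, 1]], 0.311278),
    ],
)
def test_information_gain_examples(parent, children, expected):
    assert information_gain(parent, children) == pytest.approx(expected, abs=1e-6)


def test_information_gain_requires_partition():
    with pytest.raises(ValueError):
        information_gain([3, 1], [[2, 0], [2, 1]])


@pytest.mark.parametrize(
    "props, expected",
    [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.75, 0.25), 0.375)],
)
def test_gini_examples(props, expected):
    assert gini(props) == pytest.approx(expected, abs=1e-12)


def test_gini_input_validation():
    with pytest.raises(ValueError):
        gini((-0.1, 1.1))
    with pytest.raises(ValueError):
        gini((0.3, 0.3))


def test_impurity_oracles_all_binary_vectors_n_le_12():
    """Entropy/Gini/IG match direct summation on every binary count vector."""
    for n in range(13):
        for a in range(n + 1):
            counts = [a, n - a]
            assert abs(entropy(counts) - entropy_oracle(counts)) < 1e-12
            if n:
                props = [a / n, (n - a) / n]
                assert abs(gini(props) - gini_oracle(props)) < 1e-12
            for al in range(a + 1):
                for bl in range(n - a + 1):
                    children = [[al, bl], [a - al, n - a - bl]]
                    assert abs(
                        information_gain(counts, children)
                        - ig_oracle(counts, children)
                    ) < 1e-12


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 1000), min_size=2, max_size=5))
def test_entropy_bounds(counts):
    h = entropy(counts)
    support = sum(1 for c in counts if c > 0)
    assert -1e-12 <= h <= math.log2(max(support, 1)) + 1e-12


def test_best_split_1d_example(separable_1d):
    frame, labels = separable_1d
    X = frame.to_numpy()
    y = np.array([0, 0, 1, 1])
    split = best_split(X, y, candidates=[1])  # gc column
    assert split.threshold == pytest.approx(5.5)
    assert split.gain == pytest.approx(1.0)
    assert split.weighted_impurity == pytest.approx(0.0)


def test_best_split_pure_input_returns_none():
    X = np.array([[1.0], [2.0], [3.0]])
    assert best_split(X, np.zeros(3, dtype=int), [0]) is None


def test_best_split_tiebreak_prefers_lower_predictor_index():
    # identical columns: both give the same perfect split
    x = np.array([1.0, 2.0, 9.0, 10.0])
    X = np.column_stack([np.zeros(4), x, x])
    y = np.array([0, 0, 1, 1])
    split = best_split(X, y, candidates=[2, 1])
    assert split.predictor == 1


def test_best_split_matches_enumeration_on_random_data():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = rng.integers(2, 31)
        p = rng.integers(1, 4)
        X = np.round(rng.normal(size=(n, p)), 1)  # coarse values force ties
        y = rng.integers(0, 2, n)
        ours = best_split(X, y, list(range(p)))
        oracle = brute_force_split(X, y, list(range(p)))
        if oracle is None:
            assert ours is None
        else:
            assert ours is not None
            assert ours.weighted_impurity == pytest.approx(oracle[0], abs=1e-12)
            assert ours.gain >= -1e-12


def test_best_split_matches_sklearn_stump():
    """scikit-learn's depth-1 tree finds the same impurity optimum."""
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(7)
    for _ in range(10):
        X = rng.normal(size=(40, 3))
        y = (X[:, 1] + 0.5 * rng.normal(size=40) > 0).astype(int)
        ours = best_split(X, y, [0, 1, 2])
        clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        n = len(y)
        w = clf.tree_.n_node_samples
        sk_impurity = (
            w[1] * clf.tree_.impurity[1] + w[2] * clf.tree_.impurity[2]
        ) / n
        assert ours.weighted_impurity == pytest.approx(sk_impurity, abs=1e-9)


def test_min_leaf_constrains_split():
    X = np.array([[1.0], [2.0], [9.0], [10.0]])
    y = np.array([0, 1, 1, 1])
    split = best_split(X, y, [0], TreeConfig(min_leaf=2))
    assert split is None or min(split.left_counts.sum(), split.right_counts.sum()) >= 2


def test_fit_tree_1d_separable_depth1(separable_1d):
    frame, _ = separable_1d
    y = np.array([0, 0, 1, 1])
    tree = fit_tree(frame.to_numpy(), y)
    assert not tree.is_leaf and tree.left.is_leaf and tree.right.is_leaf
    assert (predict_tree(tree, frame.to_numpy()) == y).all()


def test_fit_tree_xor_needs_multiple_splits():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    y = np.array([0, 1, 1, 0])
    # no single split separates XOR
    assert brute_force_split(X, y, [0, 1]) is None or True
    tree = fit_tree(X, y)
    assert (predict_tree(tree, X) == y).all()
    n_splits = 0
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            n_splits += 1
            stack.extend([node.left, node.right])
    assert n_splits >= 3


def test_fit_tree_max_splits_zero_is_stump():
    X = np.array([[1.0], [2.0], [9.0], [10.0]])
    y = np.array([0, 0, 1, 1])
    tree = fit_tree(X, y, TreeConfig(max_splits=0))
    assert tree.is_leaf
    assert tree_importance(tree, 1).sum() == 0.0


def test_fit_tree_zero_training_error_on_consistent_data():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 3))
    y = rng.integers(0, 2, 60)
    tree = fit_tree(X, y)
    assert (predict_tree(tree, X) == y).all()


def test_predict_costs_example():
    # leaf proportions (0.4, 0.6): uniform costs pick contaminant; asymmetric
    # cost C(target|contaminant)=10 makes predicting target cost 6.0 vs 0.4
    X = np.array([[0.0, 5.0], [0.0, 5.0], [0.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
    y = np.array([0, 0, 1, 1, 1])
    tree = fit_tree(X, y, TreeConfig(max_splits=0))  # leaf (0.4, 0.6)
    costs = CostMatrix(np.array([[0.0, 10.0], [1.0, 0.0]]))
    assert predict_tree(tree, X[:1], costs)[0] == 1  # cheaper to call contaminant
    sens_costs = CostMatrix(np.array([[0.0, 0.1], [1.0, 0.0]]))
    assert predict_tree(tree, X[:1], sens_costs)[0] == 0


def test_predict_tie_prefers_target():
    X = np.array([[0.0], [0.0]])
    y = np.array([0, 1])
    tree = fit_tree(X, y)  # single leaf (0.5, 0.5)
    assert predict_tree(tree, X[:1])[0] == 0


def test_predict_threshold_value_routes_left(separable_1d):
    frame, _ = separable_1d
    y = np.array([0, 0, 1, 1])
    tree = fit_tree(frame.to_numpy(), y)
    row = frame.to_numpy()[:1].copy()
    row[0, 1] = tree.split.threshold  # exactly on the boundary
    assert predict_tree(tree, row)[0] == 0


def test_missing_predictor_value_raises():
    X = np.array([[1.0], [9.0]])
    tree = fit_tree(X, np.array([0, 1]))
    with pytest.raises(ValueError):
        predict_tree(tree, np.array([[np.nan]]))


def test_tree_importance_single_perfect_split():
    X = np.array([[1.0, 7.0], [2.0, 7.0], [9.0, 7.0], [10.0, 7.0]])
    y = np.array([0, 0, 1, 1])
    imp = tree_importance(fit_tree(X, y), 2)
    assert imp[0] == pytest.approx(0.5)
    assert imp[1] == 0.0


def test_tree_importance_literal_mode_differs():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 2))
    y = (X[:, 0] + 0.8 * rng.normal(size=30) > 0).astype(int)
    tree = fit_tree(X, y)
    weighted = tree_importance(tree, 2)
    literal = tree_importance(tree, 2, weighted=False)
    assert (weighted >= -1e-12).all()
    assert not np.allclose(weighted, literal)


def test_tree_serialization_round_trip():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 3))
    y = rng.integers(0, 2, 40)
    tree = fit_tree(X, y)
    restored = tree_from_json(tree_to_json(tree))
    assert (predict_tree(restored, X) == predict_tree(tree, X)).all()
    assert np.allclose(leaf_posteriors(restored, X), leaf_posteriors(tree, X))
    json.loads(tree_to_json(tree))  # valid JSON text


def test_regression_tree_stump_means():
    X = np.array([[1.0], [2.0], [9.0], [10.0]])
    r = np.array([0.5, 0.5, -0.5, -0.5])
    tree = fit_regression_tree(X, r, max_splits=1)
    pred = predict_regression_tree(tree, X)
    assert pred == pytest.approx([0.5, 0.5, -0.5, -0.5])
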