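"""Classification and regression tree (CART) core.

Implements the impurity functionals used to grow binary decision trees over
per-scaffold predictor variables: Shannon entropy ``H(S) = -sum_x p_x log2 p_x``
and the information gain of a candidate partition, Gini's diversity index
``G = sum_i p_i (1 - p_i)``, exhaustive threshold search, recursive tree
growth, cost-sensitive leaf classification
``yhat = argmin_y sum_k P(k|x) C(y|k)``, and Gini variable importance.

Everything here operates on plain numpy arrays; the scaffold-aware, pandas
facing layer lives in :mod:`decontree.models`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Canonical predictor column order. Split-search tie-breaks and the
#: predictor-subset sweep both refer to this order.
PREDICTOR_NAMES = (
    "length",
    "gc",
    "dna_mean_depth",
    "rna_mean_depth",
    "dna_breadth",
    "rna_breadth",
    "dna_read_gc",
    "rna_read_gc",
)

#: Canonical class order: the target organism first, contaminants second.
#: Ties in classification are resolved toward the lower index (target).
CLASS_NAMES = ("target", "contaminant")

_EPS = 1e-12


def _as_count_vector(counts) -> np.ndarray:
    """Accept a mapping keyed by class name, or a sequence, of counts."""
    if isinstance(counts, Mapping):
        vec = np.asarray([counts.get(c, 0) for c in CLASS_NAMES], dtype=float)
        extra = set(counts) - set(CLASS_NAMES)
        if extra:
            vec = np.concatenate([vec, [counts[k] for k in sorted(extra)]])
    else:
        vec = np.asarray(list(counts), dtype=float)
    if np.any(vec < 0):
        raise ValueError("class counts must be non-negative")
    return vec


def entropy(counts) -> float:
    """Shannon entropy in bits of a class-count vector.

    ``H = -sum_x p_x log2 p_x`` with the convention ``0 log2 0 = 0``;
    an empty set has zero entropy.
    """
    vec = _as_count_vector(counts)
    n = vec.sum()
    if n == 0:
        return 0.0
    p = vec[vec > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(parent, children: Iterable) -> float:
    """Information gain of partitioning ``parent`` into ``children``.

    ``IG = H(parent) - sum_t p(t) H(t)`` where ``p(t)`` is the fraction of
    the parent's observations falling in child ``t``. The children must
    partition the parent exactly (counts sum class-wise).
    """
    pvec = _as_count_vector(parent)
    cvecs = [_as_count_vector(c) for c in children]
    if not cvecs:
        raise ValueError("at least one child subset required")
    total = np.zeros_like(pvec)
    for c in cvecs:
        if c.shape != pvec.shape:
            raise ValueError("child count vector shape differs from parent")
        total = total + c
    if not np.array_equal(total, pvec):
        raise ValueError("children do not partition the parent counts")
    n = pvec.sum()
    if n == 0:
        return 0.0
    h_children = sum((c.sum() / n) * entropy(c) for c in cvecs)
    return entropy(pvec) - h_children


def gini(proportions) -> float:
    """Gini's diversity index ``G = sum_i p_i (1 - p_i)`` of class fractions."""
    p = np.asarray(list(proportions), dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    return float((p * (1.0 - p)).sum())


def gini_from_counts(counts) -> float:
    """Gini index of a count vector; an empty set is pure by convention."""
    vec = _as_count_vector(counts)
    n = vec.sum()
    if n == 0:
        return 0.0
    return gini(vec / n)


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs ``C(y|k)``: cost of predicting y when truth is k.

    Stored as an array indexed ``[y, k]``. The diagonal must be zero and
    off-diagonal entries non-negative. ``uniform(K)`` gives 0/1 costs, under
    which cost-minimizing classification reduces to the majority class.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("cost matrix must be square")
        if np.any(np.diag(v) != 0):
            raise ValueError("cost of a correct prediction must be 0")
        if np.any(v < 0):
            raise ValueError("costs must be non-negative")
        object.__setattr__(self, "values", v)

    @classmethod
    def uniform(cls, n_classes: int = 2) -> "CostMatrix":
        return cls(np.ones((n_classes, n_classes)) - np.eye(n_classes))


@dataclass(frozen=True)
class TreeConfig:
    """Growth parameters for a single tree.

    criterion: "gini" minimizes n-weighted child Gini impurity; "entropy"
    maximizes information gain. min_leaf is the minimum observations per
    child. max_splits caps the total number of splits in the tree, counted
    breadth-first (None = grow to purity).
    """

    criterion: str = "gini"
    min_leaf: int = 1
    max_splits: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.criterion not in ("gini", "entropy"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_splits is not None and self.max_splits < 0:
            raise ValueError("max_splits must be >= 0 or None")


@dataclass
class SplitCandidate:
    """A scored axis-aligned split: rows with value <= threshold go left."""

    predictor: int  # column index into the feature matrix
    threshold: float
    left_counts: np.ndarray
    right_counts: np.ndarray
    gain: float  # information gain in bits
    weighted_impurity: float  # n-weighted mean child Gini


@dataclass
class TreeNode:
    """A node of a fitted binary tree.

    Internal nodes carry a split and two children; leaves carry class
    proportions (the posterior estimate P(k|x) for rows routed here).
    """

    n: int
    counts: np.ndarray
    split: Optional[SplitCandidate] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def proportions(self) -> np.ndarray:
        if self.n == 0:
            return np.full(len(self.counts), 1.0 / len(self.counts))
        return self.counts / self.n

    @property
    def node_gini(self) -> float:
        return gini_from_counts(self.counts)


def _entropy_vec(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise entropy of an (m, k) count matrix with row totals n."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n[:, None]
        terms = np.where(counts > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=1)


def _gini_vec(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise Gini index 1 - sum p^2 of an (m, k) count matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - (counts**2).sum(axis=1) / (n**2)
    return np.where(n > 0, g, 0.0)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    config: TreeConfig = TreeConfig(),
    n_classes: int = 2,
    allow_zero_gain: bool = False,
) -> Optional[SplitCandidate]:
    """Exhaustively search candidate predictors for the best binary split.

    Thresholds are midpoints between consecutive distinct sorted values of
    each candidate predictor. The winner minimizes n-weighted child Gini
    (criterion "gini") or maximizes information gain ("entropy"); ties break
    toward the lower candidate column index, then the lower threshold.
    Returns None when no split improves on the parent or satisfies min_leaf.
    ``allow_zero_gain`` admits non-improving splits of an impure node (used
    to finish growing e.g. XOR-patterned regions where no single split
    helps but a pair of them separates the classes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2 or not len(candidates):
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    parent_counts = onehot.sum(axis=0)
    if config.criterion == "gini":
        parent_score = gini_from_counts(parent_counts)
    else:
        parent_score = 0.0  # gain baseline; larger gain = better

    best = None  # (score, col, threshold, left_counts)
    for col in sorted(candidates):
        x = X[:, col]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cum = np.cumsum(onehot[order], axis=0)
        # split after position i-1: left = first i rows
        i = np.arange(1, n)
        valid = xs[1:] > xs[:-1]
        if config.min_leaf > 1:
            valid &= (i >= config.min_leaf) & (n - i >= config.min_leaf)
        if not valid.any():
            continue
        idx = i[valid]
        left = cum[idx - 1]
        right = parent_counts[None, :] - left
        nl = idx.astype(float)
        nr = (n - idx).astype(float)
        if config.criterion == "gini":
            score = (nl * _gini_vec(left, nl) + nr * _gini_vec(right, nr)) / n
        else:
            score = (nl * _entropy_vec(left, nl) + nr * _entropy_vec(right, nr)) / n
            score = score - entropy(parent_counts)  # = -gain; minimize
        j = int(np.argmin(score))  # first occurrence -> lowest threshold
        if best is None or score[j] < best[0] - _EPS:
            pos = idx[j]
            thr = 0.5 * (xs[pos - 1] + xs[pos])
            best = (float(score[j]), col, thr, left[j].copy())

    if best is None:
        return None
    impure = gini_from_counts(parent_counts) > _EPS
    score, col, thr, left_counts = best
    if config.criterion == "gini":
        if parent_score - score <= _EPS and not (allow_zero_gain and impure):
            return None
        weighted = score
    else:
        if -score <= _EPS and not (allow_zero_gain and impure):  # gain
            return None
        nl = left_counts.sum()
        nr = n - nl
        weighted = (
            nl * gini_from_counts(left_counts)
            + nr * gini_from_counts(parent_counts - left_counts)
        ) / n
    right_counts = parent_counts - left_counts
    gain = information_gain(parent_counts, [left_counts, right_counts])
    return SplitCandidate(
        predictor=col,
        threshold=float(thr),
        left_counts=left_counts,
        right_counts=right_counts,
        gain=gain,
        weighted_impurity=float(weighted),
    )


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: TreeConfig = TreeConfig(),
    candidates: Optional[Sequence[int]] = None,
    n_classes: int = 2,
    candidate_sampler=None,
) -> TreeNode:
    """Grow a binary classification tree breadth-first.

    Growth at a node stops when it is pure, no candidate split improves
    impurity, children would fall below min_leaf, or the tree-wide
    max_splits budget is exhausted. ``candidate_sampler``, when given, is
    called per node with the full candidate list and returns the subset to
    search (random-forest per-split predictor sampling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot fit a tree to an empty training set")
    if candidates is None:
        candidates = list(range(X.shape[1]))

    def make_node(idx: np.ndarray) -> TreeNode:
        counts = np.bincount(y[idx], minlength=n_classes).astype(float)
        return TreeNode(n=len(idx), counts=counts)

    root_idx = np.arange(len(y))
    root = make_node(root_idx)
    budget = config.max_splits
    queue = [(root, root_idx)]
    while queue:
        node, idx = queue.pop(0)
        if budget is not None and budget <= 0:
            continue
        if np.count_nonzero(node.counts) <= 1:
            continue  # pure
        cand = candidates if candidate_sampler is None else candidate_sampler(candidates)
        split = best_split(X[idx], y[idx], cand, config, n_classes)
        if split is None:
            # an impure node can still be separable by a pair of splits
            # (XOR-like structure) even when no single split reduces
            # impurity; fall back to the best zero-gain partition
            split = best_split(X[idx], y[idx], cand, config, n_classes,
                               allow_zero_gain=True)
        if split is None:
            continue
        mask = X[idx, split.predictor] <= split.threshold
        left_idx, right_idx = idx[mask], idx[~mask]
        node.split = split
        node.left = make_node(left_idx)
        node.right = make_node(right_idx)
        if budget is not None:
            budget -= 1
        queue.append((node.left, left_idx))
        queue.append((node.right, right_idx))
    return root


def _route(tree: TreeNode, X: np.ndarray) -> list[TreeNode]:
    """Leaf reached by each row; values equal to a threshold go left."""
    leaves = [None] * len(X)
    stack = [(tree, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            for i in idx:
                leaves[i] = node
            continue
        mask = X[idx, node.split.predictor] <= node.split.threshold
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return leaves


def predict_tree(
    tree: TreeNode,
    X: np.ndarray,
    costs: Optional[CostMatrix] = None,
) -> np.ndarray:
    """Cost-minimizing class index for each row.

    Routes each row to its leaf and returns
    ``argmin_y sum_k P(k|x) C(y|k)`` with ties toward the lower class
    index; with uniform costs this is the majority class of the leaf.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictor matrix contains missing values")
    k = len(tree.counts)
    cm = (costs or CostMatrix.uniform(k)).values
    if cm.shape[0] != k:
        raise ValueError("cost matrix size does not match number of classes")
    leaves = _route(tree, X)
    out = np.empty(len(X), dtype=int)
    for i, leaf in enumerate(leaves):
        expected = cm @ leaf.proportions  # expected[y] = sum_k C(y|k) P(k|x)
        out[i] = int(np.argmin(expected))
    return out


def leaf_posteriors(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Per-row leaf class-proportion vectors (n, k)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictor matrix contains missing values")
    return np.vstack([leaf.proportions for leaf in _route(tree, X)])


def tree_importance(
    tree: TreeNode, n_predictors: int, weighted: bool = True
) -> np.ndarray:
    """Gini importance per predictor.

    Default mode sums, over each predictor's splits, the node-fraction-scaled
    weighted impurity decrease ``(n_node/n_root) * (G_parent - (n_L/n) G_L -
    (n_R/n) G_R)``, which is non-negative by construction. ``weighted=False``
    instead sums the literal unweighted differences
    ``G_parent - G_left - G_right``, which can be negative.
    """
    imp = np.zeros(n_predictors)
    root_n = tree.n
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        gl = node.left.node_gini
        gr = node.right.node_gini
        if weighted:
            wl = node.left.n / node.n
            wr = node.right.n / node.n
            delta = (node.n / root_n) * (node.node_gini - wl * gl - wr * gr)
        else:
            delta = node.node_gini - gl - gr
        imp[node.split.predictor] += delta
        stack.extend([node.left, node.right])
    return imp


# ---------------------------------------------------------------------------
# Serialization: human-readable JSON round-trip


def tree_to_dict(tree: TreeNode) -> dict:
    d = {"n": int(tree.n), "counts": [float(c) for c in tree.counts]}
    if tree.is_leaf:
        d["leaf"] = True
    else:
        d["predictor"] = int(tree.split.predictor)
        d["threshold"] = tree.split.threshold
        d["gain"] = tree.split.gain
        d["weighted_impurity"] = tree.split.weighted_impurity
        d["left"] = tree_to_dict(tree.left)
        d["right"] = tree_to_dict(tree.right)
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(n=int(d["n"]), counts=np.asarray(d["counts"], dtype=float))
    if not d.get("leaf"):
        left = tree_from_dict(d["left"])
        right = tree_from_dict(d["right"])
        node.split = SplitCandidate(
            predictor=int(d["predictor"]),
            threshold=float(d["threshold"]),
            left_counts=left.counts,
            right_counts=right.counts,
            gain=float(d["gain"]),
            weighted_impurity=float(d["weighted_impurity"]),
        )
        node.left, node.right = left, right
    return node


def tree_to_json(tree: TreeNode) -> str:
    return json.dumps(tree_to_dict(tree), indent=1, sort_keys=True)


def tree_from_json(text: str) -> TreeNode:
    return tree_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Regression trees (squared-error splits) — the base learner for boosting


@dataclass
class RegressionNode:
    n: int
    value: float  # mean response of rows routed here
    predictor: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["RegressionNode"] = None
    right: Optional["RegressionNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None


def _best_reg_split(X, r, candidates, min_leaf):
    """Squared-error-minimizing split; same midpoint/tie conventions."""
    n = len(r)
    best = None
    total_s = r.sum()
    total_ss = (r**2).sum()
    base = total_ss - total_s**2 / n
    for col in sorted(candidates):
        x = X[:, col]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        rs = r[order]
        cs = np.cumsum(rs)
        css = np.cumsum(rs**2)
        i = np.arange(1, n)
        valid = xs[1:] > xs[:-1]
        valid &= (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        idx = i[valid]
        nl = idx.astype(float)
        nr = n - nl
        sl = cs[idx - 1]
        ssl = css[idx - 1]
        sse = (ssl - sl**2 / nl) + ((total_ss - ssl) - (total_s - sl) ** 2 / nr)
        j = int(np.argmin(sse))
        if best is None or sse[j] < best[0] - _EPS:
            pos = idx[j]
            best = (float(sse[j]), col, 0.5 * (xs[pos - 1] + xs[pos]))
    if best is None or base - best[0] <= _EPS:
        return None
    return best[1], best[2]


def fit_regression_tree(
    X: np.ndarray,
    r: np.ndarray,
    max_splits: int = 2,
    min_leaf: int = 1,
    candidates: Optional[Sequence[int]] = None,
) -> RegressionNode:
    """Shallow squared-error regression tree, breadth-first split budget."""
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    if candidates is None:
        candidates = list(range(X.shape[1]))
    root_idx = np.arange(len(r))
    root = RegressionNode(n=len(r), value=float(r.mean()))
    budget = max_splits
    queue = [(root, root_idx)]
    while queue:
        node, idx = queue.pop(0)
        if budget <= 0 or len(idx) < 2 * min_leaf or np.ptp(r[idx]) < _EPS:
            continue
        found = _best_reg_split(X[idx], r[idx], candidates, min_leaf)
        if found is None:
            continue
        col, thr = found
        mask = X[idx, col] <= thr
        node.predictor, node.threshold = col, float(thr)
        node.left = RegressionNode(n=int(mask.sum()), value=float(r[idx[mask]].mean()))
        node.right = RegressionNode(
            n=int((~mask).sum()), value=float(r[idx[~mask]].mean())
        )
        budget -= 1
        queue.append((node.left, idx[mask]))
        queue.append((node.right, idx[~mask]))
    return root


def predict_regression_tree(tree: RegressionNode, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X))
    stack = [(tree, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            out[idx] = node.value
            continue
        mask = X[idx, node.predictor] <= node.threshold
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return out


def regression_tree_to_dict(tree: RegressionNode) -> dict:
    d = {"n": int(tree.n), "value": tree.value}
    if not tree.is_leaf:
        d["predictor"] = int(tree.predictor)
        d["threshold"] = tree.threshold
        d["left"] = regression_tree_to_dict(tree.left)
        d["right"] = regression_tree_to_dict(tree.right)
    return d


def regression_tree_from_dict(d: dict) -> RegressionNode:
    node = RegressionNode(n=int(d["n"]), value=float(d["value"]))
    if "predictor" in d:
        node.predictor = int(d["predictor"])
        node.threshold = float(d["threshold"])
        node.left = regression_tree_from_dict(d["left"])
        node.right = regression_tree_from_dict(d["right"])
    return node
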