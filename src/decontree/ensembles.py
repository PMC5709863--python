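"""Tree ensembles: bootstrap aggregation, random forests and boosting.

Bagging fits one unpruned tree per bootstrap resample and averages the leaf
posteriors, ``f_bag(x) = (1/B) sum_b f*b(x)``. The random forest is the same
construction with a fresh random subset of m of the p predictors drawn at
every split; with m = p (and shared bootstrap streams) it reproduces bagging
tree-for-tree. Boosting fits shallow squared-error regression trees to the
residuals of the 0/1 target indicator, accumulating
``F <- F + shrinkage * tree`` from the base rate ``F0 = mean(y)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cart import (
    CLASS_NAMES,
    RegressionNode,
    TreeConfig,
    TreeNode,
    fit_regression_tree,
    fit_tree,
    leaf_posteriors,
    predict_regression_tree,
    regression_tree_from_dict,
    regression_tree_to_dict,
    tree_from_dict,
    tree_importance,
    tree_to_dict,
)

#: Classification threshold on the target score; ties classify as target,
#: consistent with sensitivity running ahead of specificity.
DEFAULT_THRESHOLD = 0.5


def _tree_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """One independent generator per tree from a master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class EnsembleModel:
    """A fitted collection of trees plus the aggregation rule.

    kind is one of "bagging", "random_forest", "boosted". For bagging and
    forests ``trees`` holds classification TreeNodes; for boosting it holds
    RegressionNodes accumulated with ``shrinkage`` from ``base_score``.
    """

    kind: str
    trees: list
    predictors: list[int]  # feature-matrix columns the model may use
    n_predictors: int
    seed: int
    m: Optional[int] = None
    shrinkage: Optional[float] = None
    base_score: Optional[float] = None
    threshold: float = DEFAULT_THRESHOLD
    predictor_names: Optional[list] = None  # columns of the fit matrix, in order

    @property
    def B(self) -> int:
        return len(self.trees)

    def target_scores(self, X: np.ndarray) -> np.ndarray:
        """Score in [0, 1] for the target class per row."""
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("predictor matrix contains missing values")
        if self.kind == "boosted":
            f = np.full(len(X), self.base_score)
            for t in self.trees:
                f += self.shrinkage * predict_regression_tree(t, X)
            return np.clip(f, 0.0, 1.0)
        scores = np.zeros(len(X))
        for t in self.trees:
            scores += leaf_posteriors(t, X)[:, 0]
        return scores / self.B

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class indices: 0 (target) where score >= threshold, else 1."""
        return np.where(self.target_scores(X) >= self.threshold, 0, 1)

    def importances(self, normalize: bool = True) -> np.ndarray:
        """Mean Gini importance over trees; normalized to sum to 1."""
        if self.kind == "boosted":
            raise ValueError("Gini importance is defined for classification trees")
        imp = np.zeros(self.n_predictors)
        for t in self.trees:
            imp += tree_importance(t, self.n_predictors)
        imp /= self.B
        if normalize:
            s = imp.sum()
            if s > 0:
                imp = imp / s
        return imp

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        enc = regression_tree_to_dict if self.kind == "boosted" else tree_to_dict
        return {
            "kind": self.kind,
            "predictors": list(self.predictors),
            "n_predictors": self.n_predictors,
            "seed": self.seed,
            "m": self.m,
            "shrinkage": self.shrinkage,
            "base_score": self.base_score,
            "threshold": self.threshold,
            "predictor_names": self.predictor_names,
            "trees": [enc(t) for t in self.trees],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        dec = regression_tree_from_dict if d["kind"] == "boosted" else tree_from_dict
        return cls(
            kind=d["kind"],
            trees=[dec(t) for t in d["trees"]],
            predictors=list(d["predictors"]),
            n_predictors=int(d["n_predictors"]),
            seed=int(d["seed"]),
            m=d.get("m"),
            shrinkage=d.get("shrinkage"),
            base_score=d.get("base_score"),
            threshold=float(d.get("threshold", DEFAULT_THRESHOLD)),
            predictor_names=d.get("predictor_names"),
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        return cls.from_dict(json.loads(text))


def fit_bagging(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    config: TreeConfig = TreeConfig(),
    seed: int = 0,
    predictors: Optional[Sequence[int]] = None,
    identity_resample: bool = False,
) -> EnsembleModel:
    """Bootstrap-aggregated trees: B resamples of size n with replacement.

    ``identity_resample`` forces every bootstrap to equal the training set
    (degenerate mode used to check that B=1 bagging equals a single tree).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if predictors is None:
        predictors = list(range(X.shape[1]))
    trees = []
    for rng in _tree_seeds(seed, B):
        idx = (
            np.arange(len(y))
            if identity_resample
            else rng.integers(0, len(y), len(y))
        )
        trees.append(fit_tree(X[idx], y[idx], config, candidates=predictors))
    return EnsembleModel(
        kind="bagging",
        trees=trees,
        predictors=list(predictors),
        n_predictors=X.shape[1],
        seed=seed,
    )


def fit_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 5000,
    m: int = 4,
    config: TreeConfig = TreeConfig(),
    seed: int = 0,
    predictors: Optional[Sequence[int]] = None,
    per_tree_sampling: bool = False,
) -> EnsembleModel:
    """Random forest: bagging with m of the p predictors sampled per split.

    ``per_tree_sampling`` draws one m-subset per tree instead of per split.
    With m equal to the number of candidate predictors the forest collapses
    to bagging (identical trees for identical bootstrap streams).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if predictors is None:
        predictors = list(range(X.shape[1]))
    if not 1 <= m <= len(predictors):
        raise ValueError(f"m must be in [1, {len(predictors)}], got {m}")
    trees = []
    for rng in _tree_seeds(seed, n_trees):
        idx = rng.integers(0, len(y), len(y))
        if per_tree_sampling:
            cand = sorted(rng.choice(predictors, size=m, replace=False).tolist())
            sampler = None
            tree = fit_tree(X[idx], y[idx], config, candidates=cand)
        else:
            if m == len(predictors):
                sampler = None  # exact bagging equivalence, same rng stream
            else:
                def sampler(cand, rng=rng):
                    return sorted(rng.choice(cand, size=m, replace=False).tolist())
            tree = fit_tree(
                X[idx], y[idx], config, candidates=predictors,
                candidate_sampler=sampler,
            )
        trees.append(tree)
    return EnsembleModel(
        kind="random_forest",
        trees=trees,
        predictors=list(predictors),
        n_predictors=X.shape[1],
        seed=seed,
        m=m,
    )


def fit_boosted(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 10,
    max_splits: int = 2,
    shrinkage: float = 0.01,
    seed: int = 0,
    predictors: Optional[Sequence[int]] = None,
    min_leaf: int = 1,
) -> EnsembleModel:
    """Residual boosting of shallow trees on the 0/1 target indicator.

    The target indicator is 1 for class index 0 (target). Each stage fits a
    regression tree with at most ``max_splits`` splits to the residual
    ``r = y_ind - F(x)`` and updates ``F <- F + shrinkage * tree``.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if predictors is None:
        predictors = list(range(X.shape[1]))
    y_ind = (y == 0).astype(float)
    f = np.full(len(y), y_ind.mean())
    trees = []
    for _ in range(n_trees):
        r = y_ind - f
        tree = fit_regression_tree(
            X, r, max_splits=max_splits, min_leaf=min_leaf, candidates=predictors
        )
        f += shrinkage * predict_regression_tree(tree, X)
        trees.append(tree)
    return EnsembleModel(
        kind="boosted",
        trees=trees,
        predictors=list(predictors),
        n_predictors=X.shape[1],
        seed=seed,
        shrinkage=shrinkage,
        base_score=float(y_ind.mean()),
    )


def predict_ensemble(model: EnsembleModel, X: np.ndarray):
    """(scores, class indices) under the model's decision threshold."""
    scores = model.target_scores(X)
    return scores, np.where(scores >= model.threshold, 0, 1)


def ensemble_importance(model: EnsembleModel) -> np.ndarray:
    """Normalized mean Gini importance per predictor (sums to 1)."""
    return model.importances(normalize=True)
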