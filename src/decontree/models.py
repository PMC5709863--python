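"""Model/Results interface over the tree learners.

A model object is built from a predictor table (pandas DataFrame, one row
per scaffold) and class labels; ``fit()`` returns a results object carrying
the fitted trees, variable importances, training diagnostics and a
``summary()`` table, with ``predict`` / ``target_scores`` / ``plot_*``
hanging off it. The numerical work is done by :mod:`decontree.cart` and
:mod:`decontree.ensembles`.

Example
-------
>>> model = BaggedTrees(table.loc[train_ids], labels.loc[train_ids], B=100, seed=1)
>>> res = model.fit()
>>> predicted = res.predict(table)      # Series of "target"/"contaminant"
>>> res.importances.sort_values(ascending=False)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import cart, ensembles
from .cart import CLASS_NAMES, PREDICTOR_NAMES, CostMatrix, TreeConfig
from .taxonomy import labels_to_indices


def _coerce_labels(labels) -> pd.Series:
    if isinstance(labels, Mapping) and not isinstance(labels, pd.Series):
        labels = pd.Series(labels)
    return pd.Series(labels).astype(str)


class _BaseTreeModel:
    """Shared data handling: align table and labels, validate predictors."""

    def __init__(self, table: pd.DataFrame, labels, predictors=None):
        labels = _coerce_labels(labels)
        missing = set(labels.index) - set(table.index)
        if missing:
            raise ValueError(f"labels refer to absent scaffolds: {sorted(missing)[:5]}")
        self.table = table.loc[labels.index]
        self.labels = labels
        if predictors is None:
            predictors = [c for c in PREDICTOR_NAMES if c in table.columns]
        unknown = set(predictors) - set(table.columns)
        if unknown:
            raise ValueError(f"predictors not in table: {sorted(unknown)}")
        # canonical order both for reproducible tie-breaks and column layout
        self.predictors = [c for c in PREDICTOR_NAMES if c in predictors] + [
            c for c in predictors if c not in PREDICTOR_NAMES
        ]
        self._X = self.table[self.predictors].to_numpy(dtype=float)
        self._y = labels_to_indices(self.labels)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str = "label", **kw):
        """Build from a single frame holding predictors plus a label column."""
        labels = frame[label_column]
        return cls(frame.drop(columns=[label_column]), labels, **kw)

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = set(self.predictors) - set(table.columns)
        if missing:
            raise ValueError(f"table lacks predictors: {sorted(missing)}")
        return table[self.predictors].to_numpy(dtype=float)


class DecisionTree(_BaseTreeModel):
    """A single CART classifier over scaffold predictor variables."""

    def __init__(self, table, labels, predictors=None, criterion="gini",
                 min_leaf=1, max_splits=None, seed=0):
        super().__init__(table, labels, predictors)
        self.config = TreeConfig(
            criterion=criterion, min_leaf=min_leaf, max_splits=max_splits, seed=seed
        )

    def fit(self) -> "TreeResults":
        tree = cart.fit_tree(self._X, self._y, self.config)
        return TreeResults(self, tree)


class BaggedTrees(_BaseTreeModel):
    """Bootstrap-aggregated trees (default B=100)."""

    kind = "bagging"

    def __init__(self, table, labels, predictors=None, B=100, criterion="gini",
                 min_leaf=1, max_splits=None, seed=0, threshold=0.5):
        super().__init__(table, labels, predictors)
        self.B = B
        self.seed = seed
        self.threshold = threshold
        self.config = TreeConfig(criterion=criterion, min_leaf=min_leaf,
                                 max_splits=max_splits, seed=seed)

    def _fit_ensemble(self):
        return ensembles.fit_bagging(
            self._X, self._y, B=self.B, config=self.config, seed=self.seed
        )

    def fit(self) -> "EnsembleResults":
        model = self._fit_ensemble()
        model.threshold = self.threshold
        model.predictor_names = list(self.predictors)
        return EnsembleResults(self, model)


class RandomForest(BaggedTrees):
    """Random forest: m of p predictors drawn afresh at every split."""

    kind = "random_forest"

    def __init__(self, table, labels, predictors=None, n_trees=5000, m=4,
                 criterion="gini", min_leaf=1, max_splits=None, seed=0,
                 threshold=0.5, per_tree_sampling=False):
        super().__init__(table, labels, predictors, B=n_trees,
                         criterion=criterion, min_leaf=min_leaf,
                         max_splits=max_splits, seed=seed, threshold=threshold)
        self.m = m
        self.per_tree_sampling = per_tree_sampling

    def _fit_ensemble(self):
        return ensembles.fit_random_forest(
            self._X, self._y, n_trees=self.B, m=self.m, config=self.config,
            seed=self.seed, per_tree_sampling=self.per_tree_sampling,
        )


class BoostedTrees(BaggedTrees):
    """Residual boosting of shallow trees (defaults: 10 trees, 2 splits,
    shrinkage 0.01)."""

    kind = "boosted"

    def __init__(self, table, labels, predictors=None, n_trees=10, max_splits=2,
                 shrinkage=0.01, min_leaf=1, seed=0, threshold=0.5):
        super().__init__(table, labels, predictors, B=n_trees,
                         min_leaf=min_leaf, max_splits=max_splits, seed=seed,
                         threshold=threshold)
        self.shrinkage = shrinkage

    def _fit_ensemble(self):
        return ensembles.fit_boosted(
            self._X, self._y, n_trees=self.B,
            max_splits=self.config.max_splits or 2,
            shrinkage=self.shrinkage, seed=self.seed,
            min_leaf=self.config.min_leaf,
        )


class _BaseResults:
    """Prediction, scoring and reporting shared by tree and ensemble fits."""

    def __init__(self, model):
        self.model = model

    def _scores(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def target_scores(self, table: pd.DataFrame) -> pd.Series:
        """Score in [0, 1] for the target class, indexed like ``table``."""
        X = self.model._matrix(table)
        return pd.Series(self._scores(X), index=table.index, name="target_score")

    def predict(self, table: pd.DataFrame, costs: Optional[CostMatrix] = None) -> pd.Series:
        raise NotImplementedError

    def score_table(self, table: pd.DataFrame) -> pd.DataFrame:
        """Predictions and scores side by side."""
        return pd.DataFrame(
            {
                "target_score": self.target_scores(table),
                "predicted_class": self.predict(table),
            }
        )

    def plot_gc_coverage(self, table: pd.DataFrame, ax=None, log_depth=True):
        """GC vs mean DNA depth scatter colored by predicted class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        pred = self.predict(table)
        for cls, color in zip(CLASS_NAMES, ("tab:blue", "tab:red")):
            sub = table[pred == cls]
            ax.scatter(sub["gc"] * 100, sub["dna_mean_depth"], s=6, alpha=0.5,
                       label=cls, color=color)
        ax.set_xlabel("GC content (%)")
        ax.set_ylabel("mean DNA depth (x)")
        if log_depth:
            ax.set_yscale("symlog")
        ax.legend()
        return ax


class TreeResults(_BaseResults):
    """A fitted single decision tree."""

    def __init__(self, model: DecisionTree, tree: cart.TreeNode):
        super().__init__(model)
        self.tree = tree

    def _scores(self, X):
        return cart.leaf_posteriors(self.tree, X)[:, 0]

    def predict(self, table, costs=None):
        X = self.model._matrix(table)
        idx = cart.predict_tree(self.tree, X, costs)
        return pd.Series([CLASS_NAMES[i] for i in idx], index=table.index,
                         name="predicted_class")

    @property
    def importances(self) -> pd.Series:
        imp = cart.tree_importance(self.tree, len(self.model.predictors))
        return pd.Series(imp, index=self.model.predictors, name="gini_importance")

    @property
    def n_splits(self) -> int:
        count = 0
        stack = [self.tree]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                count += 1
                stack.extend([node.left, node.right])
        return count

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(cart.tree_to_json(self.tree))

    def summary(self) -> str:
        lines = [
            "Decision tree classifier",
            f"  training scaffolds: {self.tree.n}",
            f"  criterion: {self.model.config.criterion}",
            f"  splits: {self.n_splits}",
            "  Gini importances:",
        ]
        for name, v in self.importances.sort_values(ascending=False).items():
            lines.append(f"    {name:<15s} {v:.4f}")
        return "\n".join(lines)


class EnsembleResults(_BaseResults):
    """A fitted bagged / random-forest / boosted model."""

    def __init__(self, model, ensemble: ensembles.EnsembleModel):
        super().__init__(model)
        self.ensemble = ensemble

    def _scores(self, X):
        return self.ensemble.target_scores(X)

    def predict(self, table, costs=None):
        scores = self.target_scores(table)
        pred = np.where(scores >= self.ensemble.threshold, CLASS_NAMES[0],
                        CLASS_NAMES[1])
        return pd.Series(pred, index=table.index, name="predicted_class")

    @property
    def importances(self) -> pd.Series:
        imp = self.ensemble.importances()
        return pd.Series(imp, index=self.model.predictors, name="gini_importance")

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.ensemble.to_json())

    def summary(self) -> str:
        e = self.ensemble
        lines = [
            f"{e.kind.replace('_', ' ').title()} model",
            f"  trees: {e.B}",
            f"  training scaffolds: {len(self.model.labels)}",
            f"  predictors: {', '.join(self.model.predictors)}",
            f"  decision threshold: {e.threshold}",
        ]
        if e.kind == "random_forest":
            lines.append(f"  m (predictors per split): {e.m}")
        if e.kind == "boosted":
            lines.append(f"  shrinkage: {e.shrinkage}; base score: {e.base_score:.4f}")
        else:
            lines.append("  Gini importances:")
            for name, v in self.importances.sort_values(ascending=False).items():
                lines.append(f"    {name:<15s} {v:.4f}")
        return "\n".join(lines)


_MODEL_KINDS = {
    "tree": DecisionTree,
    "bagging": BaggedTrees,
    "random_forest": RandomForest,
    "boosted": BoostedTrees,
}


def make_model(kind: str, table: pd.DataFrame, labels, **hyperparams):
    """Factory used by the pipeline and sweep drivers."""
    try:
        cls = _MODEL_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(_MODEL_KINDS)}")
    return cls(table, labels, **hyperparams)
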