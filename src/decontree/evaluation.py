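"""Model evaluation: confusion counts, accuracy/sensitivity/specificity,
and the two replicate sweep experiments (training fraction 1-99%; models on
the top-k most important predictors, k = 2..8).

Target-organism scaffolds are the positive class, contaminants the
negative class, so sensitivity = TP/(TP+FN) is the fraction of target
scaffolds retained and specificity = TN/(TN+FP) the fraction of
contaminants removed. Error is the misclassified fraction of the test set
and accuracy = 1 - error. Replicate seeds are derived from the master seed
as SeedSequence([master, axis_index, replicate]) so any single replicate is
individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cart import CLASS_NAMES, PREDICTOR_NAMES
from .models import make_model
from .taxonomy import LabeledDataset, split_training

METRIC_NAMES = ("accuracy", "error", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    error: float
    accuracy: float
    sensitivity: Optional[float]  # None when no positives in truth
    specificity: Optional[float]  # None when no negatives in truth


def confusion(predictions: pd.Series, truth: pd.Series) -> ConfusionCounts:
    """Confusion counts with the target class as positive.

    ``predictions`` and ``truth`` must cover the same scaffold ids, and
    truth must contain only target/contaminant (unknowns are excluded
    upstream — they have no truth to score against).
    """
    predictions = pd.Series(predictions).astype(str)
    truth = pd.Series(truth).astype(str)
    if set(predictions.index) != set(truth.index):
        raise ValueError("prediction and truth id sets differ")
    bad = set(truth) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"truth contains non-class labels: {bad}")
    truth = truth.loc[predictions.index]
    target = CLASS_NAMES[0]
    p_pos = predictions == target
    t_pos = truth == target
    return ConfusionCounts(
        TP=int((p_pos & t_pos).sum()),
        FP=int((p_pos & ~t_pos).sum()),
        TN=int((~p_pos & ~t_pos).sum()),
        FN=int((~p_pos & t_pos).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy/error/sensitivity/specificity from confusion counts.

    A metric with a zero denominator is reported as None (undefined), never
    silently as 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty test set")
    error = (c.FP + c.FN) / c.total
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    return MetricSet(error=error, accuracy=1.0 - error,
                     sensitivity=sens, specificity=spec)


@dataclass
class SweepReport:
    """Mean/std of each metric along an experimental axis.

    ``records`` retains every per-replicate measurement so aggregates can
    always be recomputed; ``failed`` counts replicates skipped because a
    random training draw contained a single class.
    """

    axis_name: str
    records: pd.DataFrame  # columns: axis value, replicate, metric columns
    replicates: int
    seed: int
    failed: int = 0

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for val, grp in self.records.groupby(self.axis_name, sort=True):
            row = {self.axis_name: val, "n_ok": len(grp)}
            for m in METRIC_NAMES:
                col = grp[m].dropna()
                row[f"{m}_mean"] = col.mean() if len(col) else math.nan
                row[f"{m}_std"] = col.std(ddof=0) if len(col) > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: Union[str, Path]) -> None:
        agg = self.aggregate()
        agg.insert(1, "n_failed", 0)
        if self.failed:
            agg["n_failed"] = self.failed
        agg.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _replicate_seed(master: int, axis_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence([master, axis_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_split(labeled: LabeledDataset, table: pd.DataFrame, split,
                   model_kind: str = "bagging",
                   predictors: Optional[Sequence[str]] = None,
                   **hyperparams) -> MetricSet:
    """Fit on the split's training ids, score its test ids."""
    labels = pd.Series(labeled.entries)
    model = make_model(model_kind, table.loc[list(split.train_ids)],
                       labels.loc[list(split.train_ids)],
                       predictors=predictors, **hyperparams)
    res = model.fit()
    test_ids = list(split.test_ids)
    pred = res.predict(table.loc[test_ids])
    return metrics(confusion(pred, labels.loc[test_ids]))


def training_fraction_sweep(
    labeled: LabeledDataset,
    table: pd.DataFrame,
    fractions: Optional[Sequence[float]] = None,
    replicates: int = 100,
    model_kind: str = "bagging",
    seed: int = 0,
    predictors: Optional[Sequence[str]] = None,
    **hyperparams,
) -> SweepReport:
    """Vary the labeled fraction used for training; replicate each point.

    Defaults to the 1-99% grid. Each (fraction, replicate) pair draws a
    fresh random partition with a seed derived from the master seed. A
    replicate whose training draw lacks a class is recorded as failed and
    excluded from the aggregates.
    """
    if fractions is None:
        fractions = [f / 100 for f in range(1, 100)]
    if any(not 0 < f < 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows, failed = [], 0
    for ai, frac in enumerate(fractions):
        for rep in range(replicates):
            rep_seed = _replicate_seed(seed, ai, rep)
            try:
                split = split_training(labeled, frac, rep_seed)
                if len({labeled.entries[i] for i in split.train_ids}) < 2:
                    failed += 1
                    continue
                ms = evaluate_split(labeled, table, split, model_kind,
                                    predictors, seed=rep_seed, **hyperparams)
            except ValueError:
                failed += 1
                continue
            rows.append({"fraction": frac, "replicate": rep,
                         "accuracy": ms.accuracy, "error": ms.error,
                         "sensitivity": ms.sensitivity,
                         "specificity": ms.specificity})
    return SweepReport(axis_name="fraction", records=pd.DataFrame(rows),
                       replicates=replicates, seed=seed, failed=failed)


def rank_predictors(
    labeled: LabeledDataset,
    table: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    B: int = 100,
) -> list[str]:
    """Predictors ordered by Gini importance of one full-predictor bagged
    model fitted on a seed-fixed split; ties broken by canonical order."""
    labels = pd.Series(labeled.entries)
    split = split_training(labeled, fraction, seed)
    model = make_model("bagging", table.loc[list(split.train_ids)],
                       labels.loc[list(split.train_ids)], B=B, seed=seed)
    imp = model.fit().importances
    order = sorted(imp.index, key=lambda c: (-imp[c], PREDICTOR_NAMES.index(c)))
    return order


def predictor_subset_sweep(
    labeled: LabeledDataset,
    table: pd.DataFrame,
    replicates: int = 1000,
    fraction: float = 0.5,
    model_kind: str = "bagging",
    seed: int = 0,
    ordering: Optional[Sequence[str]] = None,
    **hyperparams,
) -> SweepReport:
    """Models on the top-k most important predictors, k = 2..8.

    Predictors are ranked once (by Gini importance of a full bagged model,
    unless an explicit ordering is supplied); each k-point is replicated
    over fresh random splits.
    """
    if ordering is None:
        ordering = rank_predictors(labeled, table, fraction, seed,
                                   B=hyperparams.get("B", 100))
    ordering = list(ordering)
    rows, failed = [], 0
    for ai, k in enumerate(range(2, len(ordering) + 1)):
        chosen = ordering[:k]
        for rep in range(replicates):
            rep_seed = _replicate_seed(seed, ai, rep)
            try:
                split = split_training(labeled, fraction, rep_seed)
                if len({labeled.entries[i] for i in split.train_ids}) < 2:
                    failed += 1
                    continue
                ms = evaluate_split(labeled, table, split, model_kind,
                                    chosen, seed=rep_seed, **hyperparams)
            except ValueError:
                failed += 1
                continue
            rows.append({"n_predictors": k, "replicate": rep,
                         "accuracy": ms.accuracy, "error": ms.error,
                         "sensitivity": ms.sensitivity,
                         "specificity": ms.specificity})
    report = SweepReport(axis_name="n_predictors", records=pd.DataFrame(rows),
                         replicates=replicates, seed=seed, failed=failed)
    report.ordering = ordering
    return report
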