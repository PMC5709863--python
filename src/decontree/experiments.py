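"""Benchmark experiments on the synthetic regimes.

These reproduce, at desk scale, the qualitative findings the method rests
on: a bagged model with all eight predictors rescues the GC-overlapping
(fungal-contaminant) regime, a GC + DNA-depth tree does not; the
well-separated regime is classified near-perfectly; bagging reduces
between-training-draw variance relative to a single tree; and accuracy
plateaus once roughly half the labeled scaffolds are used for training.
Each function derives all randomness from the given seed(s).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import confusion, metrics, training_fraction_sweep
from .models import BaggedTrees, DecisionTree
from .simulate import simulate_blast_labels, simulate_predictor_table
from .taxonomy import split_training


def _dataset(preset: str, seed: int, n_target: int, n_contam: int):
    table, truth = simulate_predictor_table(preset, seed, n_target, n_contam)
    from .simulate import load_preset

    p = load_preset(preset)
    labels = simulate_blast_labels(truth, p.unknown_fraction, p.label_noise, seed)
    return table, labels


def overlapping_benchmark(
    seeds: Sequence[int] = range(1, 11),
    n_target: int = 1000,
    n_contam: int = 1000,
    B: int = 100,
) -> pd.DataFrame:
    """Per-seed held-out metrics on the overlapping (fungal) regime.

    For each seed: draw the dataset, take a 50% random labeled split, fit
    (a) a B-tree bagged model on all eight predictors and (b) a single tree
    restricted to gc + dna_mean_depth, and score the held-out half.
    """
    rows = []
    for seed in seeds:
        table, labels = _dataset("overlapping", seed, n_target, n_contam)
        split = split_training(labels, 0.5, seed)
        lab = pd.Series(labels.entries)
        tr, te = list(split.train_ids), list(split.test_ids)
        full = BaggedTrees(table.loc[tr], lab.loc[tr], B=B, seed=seed).fit()
        m_full = metrics(confusion(full.predict(table.loc[te]), lab.loc[te]))
        pair = DecisionTree(table.loc[tr], lab.loc[tr],
                            predictors=["gc", "dna_mean_depth"], seed=seed).fit()
        m_pair = metrics(confusion(pair.predict(table.loc[te]), lab.loc[te]))
        rows.append({"seed": seed, "accuracy_8pred": m_full.accuracy,
                     "error_2pred": m_pair.error})
    return pd.DataFrame(rows)


def separable_benchmark(
    seeds: Sequence[int] = range(1, 11),
    n_target: int = 3000,
    n_contam: int = 1000,
    B: int = 100,
) -> pd.DataFrame:
    """Per-seed held-out accuracy/sensitivity/specificity on the
    well-separated regime with an 8-predictor bagged model."""
    rows = []
    for seed in seeds:
        table, labels = _dataset("separable", seed, n_target, n_contam)
        split = split_training(labels, 0.5, seed)
        lab = pd.Series(labels.entries)
        tr, te = list(split.train_ids), list(split.test_ids)
        res = BaggedTrees(table.loc[tr], lab.loc[tr], B=B, seed=seed).fit()
        m = metrics(confusion(res.predict(table.loc[te]), lab.loc[te]))
        rows.append({"seed": seed, "accuracy": m.accuracy,
                     "sensitivity": m.sensitivity, "specificity": m.specificity})
    return pd.DataFrame(rows)


def variance_reduction_experiment(
    seed: int = 1,
    n_draws: int = 100,
    n_target: int = 500,
    n_contam: int = 500,
    B: int = 100,
) -> dict:
    """Std of held-out accuracy across random 50% training draws, single
    tree vs bagged model, on the separable regime."""
    table, labels = _dataset("separable", seed, n_target, n_contam)
    lab = pd.Series(labels.entries)
    acc_tree, acc_bag = [], []
    for draw in range(n_draws):
        draw_seed = int(
            np.random.SeedSequence([seed, draw]).generate_state(1)[0] % 2**31
        )
        split = split_training(labels, 0.5, draw_seed)
        tr, te = list(split.train_ids), list(split.test_ids)
        tree = DecisionTree(table.loc[tr], lab.loc[tr], seed=draw_seed).fit()
        acc_tree.append(
            metrics(confusion(tree.predict(table.loc[te]), lab.loc[te])).accuracy
        )
        bag = BaggedTrees(table.loc[tr], lab.loc[tr], B=B, seed=draw_seed).fit()
        acc_bag.append(
            metrics(confusion(bag.predict(table.loc[te]), lab.loc[te])).accuracy
        )
    return {
        "tree_std": float(np.std(acc_tree)),
        "bagging_std": float(np.std(acc_bag)),
        "tree_mean": float(np.mean(acc_tree)),
        "bagging_mean": float(np.mean(acc_bag)),
        "n_draws": n_draws,
    }


def plateau_experiment(
    seed: int = 1,
    fractions: Sequence[float] = (0.02, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 0.99),
    replicates: int = 20,
    n_target: int = 1000,
    n_contam: int = 1000,
    B: int = 30,
) -> pd.DataFrame:
    """Mean accuracy vs training fraction on the overlapping regime."""
    table, labels = _dataset("overlapping", seed, n_target, n_contam)
    report = training_fraction_sweep(labels, table, list(fractions), replicates,
                                     "bagging", seed, B=B)
    return report.aggregate()
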