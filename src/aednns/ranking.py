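"""Leave-one-feature-out importance ranking and recursive elimination.

A feature's importance is the drop in cross-validated accuracy when it
is removed: a baseline model is trained on all features, then one model
per feature with that feature left out, and features are ranked by
descending accuracy drop (rank 1 = most important).  Recursive
elimination then removes the lowest-ranked features cumulatively, one
more per step, retraining each time, down to a single surviving
feature.

Accuracies are CV means with a fixed seed (``single_split=True`` uses
one stratified half split instead, the cheaper and noisier variant).
Both procedures work against any trainer honoring the fit/predict
contract, not just the dual-DNN method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FEATURE_ORDER
from .evaluation import cross_validate
from .preprocessing import make_folds
from .risk_model import _labels_from_table

__all__ = ["RankingTable", "EliminationTable", "rank_by_elimination", "recursive_elimination"]


@dataclass
class RankingTable:
    """Per-feature leave-one-out accuracies and ranks."""

    table: pd.DataFrame  # index: feature; columns: accuracy_without, delta_from_baseline, rank
    baseline_accuracy: float

    def removal_order(self) -> list[str]:
        """Features from least to most important (rank d first)."""
        return list(self.table.sort_values("rank", ascending=False).index)


@dataclass
class EliminationTable:
    """Cumulative-removal accuracies, one step per removed feature."""

    table: pd.DataFrame  # columns: removed_feature, accuracy, delta_from_baseline
    baseline_accuracy: float


def _cv_accuracy(trainer_factory, data, features, k, seed, single_split):
    trainer = trainer_factory(features)
    y = _labels_from_table(data)
    folds = make_folds(len(data), 2 if single_split else k, y, seed=seed)
    if single_split:
        # score only the second half against a fit on the first
        model = trainer.fit(
            data.iloc[folds.train_indices(1)].reset_index(drop=True), seed=seed
        )
        test = data.iloc[folds.test_indices(1)].reset_index(drop=True)
        y_pred = np.asarray(model.predict_label(test), dtype=int)
        return float(np.mean(y_pred == y[folds.test_indices(1)]))
    report = cross_validate(trainer, data, folds, seed=seed)
    return report.mean_metric("accuracy")


def rank_by_elimination(
    data: pd.DataFrame,
    trainer_factory,
    k: int = 5,
    seed: int = 0,
    features: list[str] | None = None,
    single_split: bool = False,
) -> RankingTable:
    """Rank features by the accuracy drop their removal causes.

    ``trainer_factory(features)`` must return a fresh trainer
    restricted to the given feature list.  Ties in the drop are broken
    by canonical feature order.
    """
    features = list(features) if features is not None else list(FEATURE_ORDER)
    if len(features) < 2:
        raise ValueError("need at least 2 features to rank")
    baseline = _cv_accuracy(trainer_factory, data, features, k, seed, single_split)
    records = []
    for feat in features:
        rest = [f for f in features if f != feat]
        acc = _cv_accuracy(trainer_factory, data, rest, k, seed, single_split)
        records.append({"feature": feat, "accuracy_without": acc})
    table = pd.DataFrame.from_records(records).set_index("feature")
    table["delta_from_baseline"] = baseline - table["accuracy_without"]
    # descending delta; ties broken by position in the canonical order
    order = np.lexsort((np.arange(len(features)), -table["delta_from_baseline"].to_numpy()))
    ranks = np.empty(len(features), dtype=int)
    ranks[order] = np.arange(1, len(features) + 1)
    table["rank"] = ranks
    return RankingTable(table=table, baseline_accuracy=baseline)


def recursive_elimination(
    data: pd.DataFrame,
    trainer_factory,
    ranking: RankingTable,
    k: int = 5,
    seed: int = 0,
    single_split: bool = False,
) -> EliminationTable:
    """Remove the lowest-ranked features cumulatively, retraining each step.

    Step j trains without the j lowest-ranked features; d - 1 steps
    leave a single (rank-1) feature at the end.
    """
    features = list(ranking.table.index)
    if len(features) < 2:
        raise ValueError("need at least 2 features to eliminate")
    removal = ranking.removal_order()
    records = []
    removed: list[str] = []
    for feat in removal[:-1]:
        removed.append(feat)
        remaining = [f for f in features if f not in removed]
        acc = _cv_accuracy(trainer_factory, data, remaining, k, seed, single_split)
        records.append(
            {
                "removed_feature": feat,
                "n_remaining": len(remaining),
                "accuracy": acc,
                "delta_from_baseline": ranking.baseline_accuracy - acc,
            }
        )
    return EliminationTable(
        table=pd.DataFrame.from_records(records),
        baseline_accuracy=ranking.baseline_accuracy,
    )
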