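"""Cross-validation harness, stability measures and baselines.

The reported SD of an accuracy summary follows the repeated-CV convention:
the sample standard deviation over the per-repeat mean accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .core_model import ExpressionDataset, Hypergraph, ParameterError
from .learning import LearningConfig, predict_dataset, train

__all__ = [
    "CVResult",
    "cross_validate",
    "appearance_count",
    "module_recovery_count",
    "knn_baseline",
    "degree_sweep",
]


@dataclass
class CVResult:
    """Accuracy summary of repeated stratified k-fold cross-validation."""

    accuracies: np.ndarray  # repeats x folds
    models: list  # models[r][f] -> Hypergraph (empty for baselines)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def per_repeat_means(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sd(self) -> float:
        """Sample SD over the repeats' mean accuracies."""
        if self.accuracies.shape[0] < 2:
            return float("nan")
        return float(self.per_repeat_means.std(ddof=1))


def _fold_splits(labels: np.ndarray, folds: int, repeats: int, seed: int):
    """Stratified fold index pairs per repeat, deterministically seeded.

    Stratification keeps every stage represented in every training fold —
    required when the rarest stage has only a handful of samples.
    """
    counts = pd.Series(labels).value_counts()
    deficient = counts[counts < folds]
    if not deficient.empty:
        raise ValueError(
            "stratified %d-fold CV impossible: stage(s) %s have fewer samples "
            "than folds" % (folds, dict(deficient))
        )
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed * 100003 + r) % 2**31
        )
        out.append(list(skf.split(np.zeros(len(labels)), labels)))
    return out


def cross_validate(
    dataset: ExpressionDataset,
    config: LearningConfig,
    folds: int = 10,
    repeats: int = 10,
) -> CVResult:
    """Repeated stratified k-fold CV of the hypergraph learner.

    Fold assignment is seeded from ``config.seed``; each (repeat, fold)
    training run gets its own derived seed so repeats are independent but
    the whole experiment is reproducible.
    """
    labels = dataset.labels.to_numpy()
    splits = _fold_splits(labels, folds, repeats, config.seed)
    acc = np.zeros((repeats, folds))
    models: list[list[Hypergraph]] = []
    for r, split in enumerate(splits):
        fold_models = []
        for f, (tr, te) in enumerate(split):
            cfg = replace(config, seed=(config.seed * 9973 + r * 101 + f) % 2**31)
            model, _ = train(dataset.subset(tr), cfg)
            test = dataset.subset(te)
            pred = predict_dataset(model, test)
            acc[r, f] = float(np.mean(pred == test.labels.to_numpy()))
            fold_models.append(model)
        models.append(fold_models)
    return CVResult(accuracies=acc, models=models)


def appearance_count(models: list[Hypergraph], feature_id: str) -> int:
    """Stability measure A(x_i): in how many models the feature appears.

    A model counts once no matter how many of its hyperedges contain the
    feature (indicator, not multiplicity).
    """
    fid = str(feature_id)
    return sum(
        1
        for m in models
        if any(fid in e.members for e in m.hyperedges)
    )


def appearance_ranking(models: list[Hypergraph]) -> pd.Series:
    """Appearance counts of every feature occurring in any model, sorted."""
    counts: dict[str, int] = {}
    for m in models:
        seen = {fid for e in m.hyperedges for fid in e.members}
        for fid in seen:
            counts[fid] = counts.get(fid, 0) + 1
    return pd.Series(counts).sort_values(ascending=False)


def module_recovery_count(per_fold_models: list[Hypergraph], target_set) -> int:
    """Number of fold models containing a hyperedge covering ``target_set``.

    A hyperedge counts when its member set is a superset of the target set.
    """
    target = {str(t) for t in target_set}
    return sum(
        1
        for m in per_fold_models
        if any(target <= set(e.members) for e in m.hyperedges)
    )


def _knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int,
    stage_order: list[str],
) -> np.ndarray:
    """Euclidean k-NN with majority vote; ties by smallest mean distance,
    then by stage order."""
    nn = NearestNeighbors(n_neighbors=k).fit(X_train)
    dist, idx = nn.kneighbors(X_test)
    preds = []
    for d_row, i_row in zip(dist, idx):
        votes = y_train[i_row]
        best, key = None, None
        for y in stage_order:
            mask = votes == y
            if not mask.any():
                continue
            cand = (-int(mask.sum()), float(d_row[mask].mean()))
            if key is None or cand < key:
                best, key = y, cand
        preds.append(best)
    return np.array(preds)


def knn_baseline(
    dataset: ExpressionDataset,
    k: int = 3,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Euclidean k-NN over the stacked miRNA+mRNA features.

    Uses the same seeded fold structure as :func:`cross_validate` given the
    same ``seed``, enabling paired comparison.
    """
    labels = dataset.labels.to_numpy()
    X = dataset.values
    splits = _fold_splits(labels, folds, repeats, seed)
    stage_order = dataset.stages
    acc = np.zeros((repeats, folds))
    for r, split in enumerate(splits):
        for f, (tr, te) in enumerate(split):
            if k >= len(tr):
                raise ParameterError(
                    f"k = {k} must be smaller than the training fold ({len(tr)})"
                )
            pred = _knn_predict(X[tr], labels[tr], X[te], k, stage_order)
            acc[r, f] = float(np.mean(pred == labels[te]))
    return CVResult(accuracies=acc, models=[])


def degree_sweep(
    dataset: ExpressionDataset,
    l_values,
    m_values,
    config: LearningConfig,
    folds: int = 10,
    repeats: int = 1,
) -> pd.DataFrame:
    """Mean CV accuracy for every (l, m) hyperedge-degree combination."""
    grid = pd.DataFrame(index=list(l_values), columns=list(m_values), dtype=float)
    for l in l_values:
        for m in m_values:
            cfg = replace(config, l=int(l), m=int(m))
            grid.loc[l, m] = cross_validate(dataset, cfg, folds, repeats).mean
    return grid
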