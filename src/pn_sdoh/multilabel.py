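"""Experiment-2 modeling: multi-label CNN evaluation, intensity SVC, correlations.

The harmonized, binarized patient table feeds the nine-layer 1-D CNN of
:mod:`pn_sdoh.cnn`; 10-fold cross-validation accumulates per-class correct
and incorrect counts (each sigmoid output thresholded at 0.5).  A support
vector classifier predicts the L/M/H/VH encounter-intensity bin from
demographics, and Pearson correlations relate attribute columns to SDoH
target columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import ConvNet1D, TrainConfig

#: Decision threshold on sigmoid outputs.
THRESHOLD = 0.5


@dataclass
class PerClassReport:
    """Correct / incorrect prediction counts per class, pooled over folds."""

    table: pd.DataFrame  # columns: class, correct, incorrect, accuracy
    n_evaluated: int

    def accuracy(self, cls: str) -> float:
        row = self.table.set_index("class").loc[cls]
        return float(row["accuracy"])


def build_network(n_features: int, n_classes: int, seed: int = 0) -> ConvNet1D:
    """Construct the fixed nine-layer network for the given problem size."""
    return ConvNet1D(n_features=n_features, n_classes=n_classes, seed=seed)


def train_eval_multilabel(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    *,
    folds: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    class_names: list[str] | None = None,
) -> PerClassReport:
    """10-fold cross-validated per-class evaluation of the CNN.

    Per fold the network trains from scratch, sigmoid outputs are
    thresholded at 0.5, and each class accumulates correct/incorrect
    counts over held-out instances (so correct + incorrect = n for every
    class).  Classes never present in a training fold are still reported.
    """
    if isinstance(Y, pd.DataFrame):
        class_names = class_names or [str(c) for c in Y.columns]
        Y = Y.to_numpy()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=int)
    n, n_classes = Y.shape
    if n < folds:
        raise ValueError(f"need at least {folds} instances, got {n}")
    class_names = class_names or [f"class_{i}" for i in range(n_classes)]
    if (Y.sum(axis=1) > 3).any():
        raise ValueError("multi-label targets must have at most 3 positive classes")

    correct = np.zeros(n_classes, dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        if Y[train_idx].sum(axis=0).min() == 0:
            missing = [class_names[i] for i in np.where(Y[train_idx].sum(axis=0) == 0)[0]]
            warnings.warn(
                f"fold {fold}: classes never positive in training: {missing}",
                stacklevel=2,
            )
        scaler = StandardScaler().fit(X[train_idx])
        net = build_network(X.shape[1], n_classes, seed=seed + fold)
        net.fit(scaler.transform(X[train_idx]), Y[train_idx], config=train_config)
        pred = net.predict(scaler.transform(X[test_idx]), threshold=THRESHOLD)
        correct += (pred == Y[test_idx]).sum(axis=0)

    table = pd.DataFrame(
        {
            "class": class_names,
            "correct": correct,
            "incorrect": n - correct,
            "accuracy": correct / n,
        }
    )
    return PerClassReport(table=table, n_evaluated=n)


def intensity_classifier(
    X: np.ndarray | pd.DataFrame,
    intensity_labels: np.ndarray | pd.Series,
    *,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """CV accuracy of an SVC predicting L/M/H/VH intensity from demographics."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(intensity_labels)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two intensity bins present")
    if counts.min() >= folds:
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in kf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        clf = SVC(random_state=seed)
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        accs.append(float(np.mean(clf.predict(scaler.transform(X[test_idx])) == y[test_idx])))
    return float(np.mean(accs))


def attribute_correlations(
    table: pd.DataFrame, sdoh_columns: list[str]
) -> pd.DataFrame:
    """Pearson r for every (attribute, SDoH) column pair, sorted by |r|.

    Zero-variance columns yield an undefined r, reported as NaN with a
    ``defined`` flag rather than silently dropped.
    """
    attr_columns = [c for c in table.columns if c not in sdoh_columns]
    rows = []
    for a in attr_columns:
        x = pd.to_numeric(table[a], errors="raise").to_numpy(dtype=float)
        for s in sdoh_columns:
            y = pd.to_numeric(table[s], errors="raise").to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {"attribute": a, "sdoh": s, "r": r, "defined": not np.isnan(r)}
            )
    df = pd.DataFrame(rows)
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["abs_r"], ascending=False, kind="mergesort").drop(columns="abs_r")
    return df.reset_index(drop=True)
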