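"""Multi-feature SVM response classification protocol.

The cohort is class-imbalanced, so the protocol first draws balanced
subsets (each class subsampled without replacement down to the minimum
class size), then per subset: an RBF-SVM grid search over
C in {2^8..2^15} and gamma in {2^-18..2^-5} by leave-one-out accuracy,
sequential forward selection down to six features, and leave-one-out
validation of the selected model.  Features selected across subsets are
pooled into a frequency histogram whose top entries form the consensus
feature set.  Standardization is fitted on the training portion of every
fold; the multiclass strategy is the SVC default one-vs-one voting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "SubsetPlan",
    "SelectionResult",
    "EvalMetrics",
    "balanced_subsets",
    "loo_accuracy",
    "grid_search_svm",
    "sfs_select",
    "consensus_features",
    "loo_evaluate",
    "run_response_classification",
]

DEFAULT_C_GRID = tuple(2.0 ** np.arange(8, 16))       # 2^8 .. 2^15
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-18, -4))  # 2^-18 .. 2^-5


@dataclass
class ClassifierConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    n_subsets: int = 10
    n_selected: int = 6
    seed: int = 0
    task: str = "three_class"  # or "responder_vs_nonresponder"

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.n_selected < 1:
            raise ValueError("n_selected must be >= 1")
        if self.task not in ("three_class", "responder_vs_nonresponder"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class SubsetPlan:
    subsets: list[np.ndarray]
    per_class_count: int
    classes: tuple[str, ...]


@dataclass
class SelectionResult:
    per_subset: list[list[str]]
    histogram: Counter
    feature_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return sum(self.histogram.values())


@dataclass
class EvalMetrics:
    accuracy: float                       # percent
    sensitivity: dict[str, float]         # percent, per class
    specificity: dict[str, float]         # percent, per class
    confusion: pd.DataFrame               # rows = true, cols = predicted


def balanced_subsets(labels, n_subsets: int, seed: int) -> SubsetPlan:
    """Random class-balanced subsets, each class drawn without replacement
    down to the minimum class size.  Deterministic under the seed."""
    labels = np.asarray(labels)
    classes = tuple(pd.unique(labels))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if any(v == 0 for v in counts.values()) or len(classes) < 2:
        raise ValueError("every class must be nonempty")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        idx = np.concatenate([
            rng.choice(np.flatnonzero(labels == c), size=m, replace=False)
            for c in classes])
        subsets.append(np.sort(idx))
    return SubsetPlan(subsets=subsets, per_class_count=m, classes=classes)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def loo_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float
                 ) -> float:
    """Leave-one-out accuracy of a standardized RBF SVC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            continue
        Xtr, Xte = _standardize(X[tr], X[i:i + 1])
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(Xtr, y[tr])
        correct += int(clf.predict(Xte)[0] == y[i])
    return correct / n


def grid_search_svm(features, labels, config: ClassifierConfig
                    ) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by leave-one-out accuracy.

    Ties resolve to the smallest C, then the smallest gamma.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs at least two classes")
    best, best_acc = None, -1.0
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            acc = loo_accuracy(X, y, C, gamma)
            if acc > best_acc:
                best, best_acc = (C, gamma), acc
    return best


def sfs_select(features: pd.DataFrame, labels, config: ClassifierConfig,
               C: float, gamma: float) -> list[str]:
    """Greedy sequential forward selection by leave-one-out accuracy.

    Adds at each step the candidate maximizing the LOO accuracy of the SVM
    on the already-selected set plus that candidate; ties go to the lowest
    column index.  Stops at ``n_selected`` features.
    """
    y = np.asarray(labels)
    cols = list(features.columns)
    n_target = config.n_selected
    if len(cols) < n_target:
        warnings.warn(f"only {len(cols)} candidate features for "
                      f"n_selected={n_target}; selecting all", stacklevel=2)
        n_target = len(cols)
    selected: list[str] = []
    X = features.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(cols)}
    while len(selected) < n_target:
        best_col, best_acc = None, -1.0
        chosen = [col_idx[c] for c in selected]
        for c in cols:
            if c in selected:
                continue
            acc = loo_accuracy(X[:, chosen + [col_idx[c]]], y, C, gamma)
            if acc > best_acc:
                best_col, best_acc = c, acc
        selected.append(best_col)
    return selected


def consensus_features(selection: SelectionResult, k: int) -> list[str]:
    """Top-k features of the cross-subset occurrence histogram.

    Ties break by the fixed feature order of the source table; a tie across
    the k-boundary (or k exceeding the number of distinct selected
    features) is warned about.
    """
    if not selection.histogram:
        raise ValueError("empty selection histogram")
    order = {c: i for i, c in enumerate(selection.feature_order)}
    ranked = sorted(selection.histogram.items(),
                    key=lambda kv: (-kv[1], order.get(kv[0], len(order))))
    if k > len(ranked):
        warnings.warn(f"k={k} exceeds {len(ranked)} distinct selected "
                      "features; returning all", stacklevel=2)
        return [name for name, _ in ranked]
    if len(ranked) > k and ranked[k - 1][1] == ranked[k][1]:
        warnings.warn("tie at the consensus cut-off; broken by fixed "
                      "feature order", stacklevel=2)
    return [name for name, _ in ranked[:k]]


def loo_evaluate(features: pd.DataFrame, labels, selected: list[str],
                 C: float, gamma: float) -> EvalMetrics:
    """Leave-one-out validation of the selected-feature SVM."""
    y = np.asarray(labels)
    classes = list(pd.unique(y))
    for c in classes:
        if np.sum(y == c) < 2:
            warnings.warn(f"class {c} has a single sample; its fold still "
                          "runs", stacklevel=2)
    X = features[selected].to_numpy(dtype=float)
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xtr, Xte = _standardize(X[tr], X[i:i + 1])
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(Xtr, y[tr])
        pred[i] = clf.predict(Xte)[0]
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        conf.loc[t, p] += 1
    acc = 100.0 * np.trace(conf.to_numpy()) / n
    sens, spec = {}, {}
    for c in classes:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    return EvalMetrics(accuracy=float(acc), sensitivity=sens,
                       specificity=spec, confusion=conf)


FEATURE_MODES = ("combined", "qus_texture", "molecular")
_MOLECULAR = ("ER", "PR", "HER2")


def _mode_columns(columns: list[str], mode: str) -> list[str]:
    if mode == "combined":
        return columns
    if mode == "qus_texture":
        return [c for c in columns if c not in _MOLECULAR]
    if mode == "molecular":
        return [c for c in columns if c in _MOLECULAR]
    raise ValueError(f"unknown mode {mode!r}; use one of {FEATURE_MODES}")


def run_response_classification(table: pd.DataFrame,
                                config: ClassifierConfig,
                                mode: str = "combined") -> dict:
    """Full protocol on one scan-time feature table.

    ``table`` needs a ``label`` column plus feature columns.  Returns the
    per-subset metrics, their mean accuracy, the selection result and the
    consensus feature list.
    """
    labels = table["label"].to_numpy()
    feat_cols = _mode_columns(
        [c for c in table.columns if c not in ("id", "label", "scan_time")],
        mode)
    features = table[feat_cols]
    if config.task == "responder_vs_nonresponder":
        labels = np.where(np.isin(labels, ["CR", "PR"]), "R", "NR")
    plan = balanced_subsets(labels, config.n_subsets, config.seed)
    per_subset_metrics, per_subset_features = [], []
    params = []
    for idx in plan.subsets:
        Xs = features.iloc[idx]
        ys = labels[idx]
        C, gamma = grid_search_svm(Xs, ys, config)
        sel = sfs_select(Xs, ys, config, C, gamma)
        per_subset_features.append(sel)
        params.append((C, gamma))
        per_subset_metrics.append(loo_evaluate(Xs, ys, sel, C, gamma))
    selection = SelectionResult(
        per_subset=per_subset_features,
        histogram=Counter(f for sel in per_subset_features for f in sel),
        feature_order=tuple(feat_cols))
    consensus = consensus_features(selection, config.n_selected)
    return {
        "mode": mode,
        "task": config.task,
        "subset_plan": plan,
        "per_subset_metrics": per_subset_metrics,
        "per_subset_params": params,
        "mean_accuracy": float(np.mean(
            [m.accuracy for m in per_subset_metrics])),
        "selection": selection,
        "consensus_features": consensus,
    }
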