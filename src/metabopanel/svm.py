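"""Greedy forward feature selection wrapping a linear-kernel SVM.

The selection starts from an empty panel; at each step every remaining
metabolite is scored by the mean held-out accuracy of a linear-kernel
maximum-margin classifier trained on the current panel plus that candidate,
under stratified 3-fold cross-validation repeated ``cv_repeats`` times with
different fold shuffles, and the arg-max (ties broken by lowest feature
index) is appended.  Selection stops when half the features are in the
path.  The reported *panel* is the shortest prefix of the path attaining
the maximum mean CV accuracy.

Performance is reported from a nested scheme so that feature selection
cannot leak into the estimate: within every repeat the same stratified
3-fold split serves as the outer loop, the greedy search is re-run on each
outer training set alone (inner 3-fold CV), and the panel found there
predicts the outer held-out samples.  The aggregated confusion matrix sums
these outer predictions over all repeats and folds, so each sample
contributes once per repeat.

Features are standardized (mean 0, sd 1) inside each training fold; the
regularization constant defaults to C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import RunConfig
from .errors import (AggregationError, ContrastError, SelectionError,
                     StageError)
from .peaktable import PeakTable


@dataclass
class SelectionPath:
    """Ordered greedy path and the reported panel prefix."""

    steps: list[tuple[str, float]]   # (metabolite added, mean CV accuracy)
    panel: list[str]
    max_steps: int


@dataclass
class ClassifierReport:
    """Aggregated confusion matrix and percent metrics over repeats x folds."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str
    repeats: int
    folds: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.total, 2)

    @property
    def sensitivity(self) -> float:
        return round(100.0 * self.tp / (self.tp + self.fn), 2)

    @property
    def specificity(self) -> float:
        return round(100.0 * self.tn / (self.tn + self.fp), 2)

    @property
    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.sensitivity, self.specificity)

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fn": self.fn,
                          "fp": self.fp, "tn": self.tn},
            "positive_class": self.positive_class,
            "repeats": self.repeats,
            "folds": self.folds,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "balanced_accuracy_pct": self.balanced_accuracy,
        }


def balanced_accuracy(sensitivity_pct: float, specificity_pct: float) -> float:
    """Arithmetic mean of (already rounded) percent sensitivity/specificity."""
    return round((sensitivity_pct + specificity_pct) / 2.0, 2)


def train_svm_lk(X: np.ndarray, y: np.ndarray, c_reg: float = 1.0):
    """Fit a linear-kernel SVM on standardized features.

    Returns ``(model, mean, std)``; apply ``model.predict((X - mean)/std)``
    to new data.  Raises for a single-class training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ContrastError("single-class training data")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    model = SVC(kernel="linear", C=c_reg)
    model.fit((X - mean) / std, y)
    return model, mean, std


def make_fold_plan(
    y: np.ndarray, folds: int, repeats: int, seed: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified folds, reshuffled per repeat with seeds derived from one
    root seed.  The same plan object is shared by the greedy scorer and any
    oracle re-implementation, making the path comparison exact."""
    ss = np.random.SeedSequence(seed).spawn(repeats)
    plans = []
    for child in ss:
        rs = int(child.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        plans.append([(tr.copy(), te.copy())
                      for tr, te in skf.split(np.zeros(len(y)), y)])
    return plans


def _standardized_folds(X: np.ndarray, plans):
    """Pre-standardize the full feature matrix per training fold."""
    cache = []
    for plan in plans:
        per_fold = []
        for tr, te in plan:
            mean = X[tr].mean(axis=0)
            std = X[tr].std(axis=0)
            std[std == 0] = 1.0
            per_fold.append(((X[tr] - mean) / std, (X[te] - mean) / std,
                             tr, te))
        cache.append(per_fold)
    return cache


def score_subset(cols: Sequence[int], y: np.ndarray, cache,
                 c_reg: float = 1.0) -> float:
    """Mean held-out accuracy of the subset over all repeats and folds."""
    cols = list(cols)
    correct = 0
    total = 0
    for per_fold in cache:
        for Ztr, Zte, tr, te in per_fold:
            model = SVC(kernel="linear", C=c_reg)
            model.fit(Ztr[:, cols], y[tr])
            pred = model.predict(Zte[:, cols])
            correct += int((pred == y[te]).sum())
            total += len(te)
    return correct / total


def _greedy_path(X: np.ndarray, y: np.ndarray, plans, max_steps: int,
                 c_reg: float = 1.0) -> list[tuple[int, float]]:
    """Greedy arg-max path over the given fold plan(s)."""
    cache = _standardized_folds(X, plans)
    m = X.shape[1]
    selected: list[int] = []
    path: list[tuple[int, float]] = []
    remaining = list(range(m))
    for _ in range(max_steps):
        best_j, best_acc = None, -1.0
        for j in remaining:  # ascending index => stable tie-break
            acc = score_subset(selected + [j], y, cache, c_reg)
            if acc > best_acc:
                best_j, best_acc = j, acc
        selected.append(best_j)
        remaining.remove(best_j)
        path.append((best_j, best_acc))
    return path


def _best_prefix(path: list[tuple[int, float]]) -> list[int]:
    accs = [a for _, a in path]
    return [j for j, _ in path[:int(np.argmax(accs)) + 1]]


def greedy_forward_select(
    table: PeakTable,
    contrast: tuple[str, str],
    config: RunConfig,
    max_steps: int | None = None,
) -> tuple[SelectionPath, ClassifierReport]:
    """Run the full greedy forward search for one contrast.

    The returned path and panel come from the whole two-group data set;
    the report comes from the nested outer evaluation described in the
    module docstring.
    """
    if table.stage != "log":
        raise StageError("greedy_forward_select expects a log-stage table")
    X, y = table.contrast_values(contrast)
    m = X.shape[1]
    if m < 2:
        raise SelectionError("need at least 2 features")
    if min((y > 0).sum(), (y < 0).sum()) < 4:
        raise SelectionError("need >= 4 samples per class")
    names = table.metabolite_names
    limit = max_steps or config.svm_max_steps or (m // 2)
    limit = min(limit, m)

    plans = make_fold_plan(y, config.cv_folds, config.cv_repeats,
                           config.rng_seed)
    raw_path = _greedy_path(X, y, plans, limit, config.svm_c)
    steps = [(names[j], acc) for j, acc in raw_path]
    panel_cols = _best_prefix(raw_path)
    path = SelectionPath(steps=steps, panel=[names[j] for j in panel_cols],
                         max_steps=limit)

    # nested outer evaluation: reselect the panel on each outer train set
    truths, preds = [], []
    inner_root = np.random.SeedSequence(config.rng_seed, spawn_key=(101,))
    inner_seeds = inner_root.generate_state(
        config.cv_repeats * config.cv_folds)
    for r, plan in enumerate(plans):
        y_pred = np.full(len(y), None, dtype=object)
        for f, (tr, te) in enumerate(plan):
            seed = int(inner_seeds[r * config.cv_folds + f] % (2 ** 31))
            inner_plans = make_fold_plan(y[tr], config.cv_folds, 1, seed)
            inner_path = _greedy_path(X[tr], y[tr], inner_plans,
                                      min(limit, m), config.svm_c)
            cols = _best_prefix(inner_path)
            model, mu, sd = train_svm_lk(X[tr][:, cols], y[tr],
                                         config.svm_c)
            y_pred[te] = model.predict((X[te][:, cols] - mu) / sd)
        truths.append(y.copy())
        preds.append(y_pred)
    report = aggregate_report(truths, preds, contrast[0],
                              repeats=config.cv_repeats,
                              folds=config.cv_folds)
    return path, report


def aggregate_report(
    truths: Sequence[np.ndarray],
    preds: Sequence[np.ndarray],
    positive_class: str,
    repeats: int,
    folds: int,
    positive_value=1,
) -> ClassifierReport:
    """Sum confusion counts over per-repeat held-out predictions.

    Each element of ``truths``/``preds`` is one repeat's full-length label
    vector; a sample never predicted within a repeat raises
    :class:`AggregationError`.
    """
    tp = fn = fp = tn = 0
    for y_true, y_pred in zip(truths, preds):
        if any(p is None for p in y_pred):
            raise AggregationError("a sample was never held out in a repeat")
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive_value
        hit = y_pred == y_true
        tp += int((pos & hit).sum())
        fn += int((pos & ~hit).sum())
        tn += int((~pos & hit).sum())
        fp += int((~pos & ~hit).sum())
    return ClassifierReport(tp=tp, fn=fn, fp=fp, tn=tn,
                            positive_class=positive_class,
                            repeats=repeats, folds=folds)
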