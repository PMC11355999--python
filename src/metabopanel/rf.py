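"""Random-forest binary classification with OOB tuning and Gini importance.

The number of trees and the maximum tree depth are chosen per contrast by
maximizing the out-of-bag (OOB) accuracy over a small grid (ties broken by
fewer trees, then shallower depth).  Performance is evaluated with the
same 10-times-repeated stratified 3-fold cross-validation used for the SVM
and aggregated into one confusion matrix.  Feature importances are mean
Gini impurity decreases of a forest trained on all samples with all
features, normalized to sum to one, averaged over ``cv_repeats`` forest
seeds by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig
from .errors import ContrastError, StageError
from .peaktable import PeakTable
from .svm import ClassifierReport, aggregate_report, make_fold_plan

DEFAULT_GRID = tuple(
    (n, d) for n in (100, 500, 1000) for d in (2, 3, 5, None))


@dataclass
class RfSettings:
    n_trees: int
    max_depth: int | None
    oob_score: float
    grid_trace: list[tuple[int, int | None, float]] = field(
        default_factory=list)


@dataclass
class ImportanceRecord:
    metabolite: str
    importance: float
    rank: int
    zero: bool = False


def _depth_key(depth: int | None) -> float:
    return float("inf") if depth is None else float(depth)


def _derive_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def tune_rf_oob(
    table: PeakTable,
    contrast: tuple[str, str],
    grid=DEFAULT_GRID,
    seed: int = 0,
) -> RfSettings:
    """Pick (n_trees, max_depth) maximizing the OOB accuracy.

    Each grid point trains one forest on all samples with bootstrap
    resampling; samples that appear in every bootstrap (no OOB trees) are
    excluded from the score by the underlying estimator with a warning.
    """
    if table.stage != "log":
        raise StageError("tune_rf_oob expects a log-stage table")
    X, y = table.contrast_values(contrast)
    if min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ContrastError("both classes need >= 2 samples")
    trace = []
    for gi, (n_trees, depth) in enumerate(grid):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_depth=depth, oob_score=True,
            bootstrap=True, random_state=_derive_seed(seed, gi), n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        trace.append((n_trees, depth, float(clf.oob_score_)))
    best = max(t[2] for t in trace)
    candidates = [t for t in trace if t[2] >= best - 1e-12]
    candidates.sort(key=lambda t: (t[0], _depth_key(t[1])))
    n_trees, depth, score = candidates[0]
    return RfSettings(n_trees=n_trees, max_depth=depth, oob_score=score,
                      grid_trace=trace)


def evaluate_rf(
    table: PeakTable,
    contrast: tuple[str, str],
    settings: RfSettings,
    config: RunConfig,
) -> ClassifierReport:
    """Repeated stratified k-fold evaluation of the tuned forest."""
    X, y = table.contrast_values(contrast)
    plans = make_fold_plan(y, config.cv_folds, config.cv_repeats,
                           config.rng_seed)
    truths, preds = [], []
    for r, plan in enumerate(plans):
        y_pred = np.full(len(y), None, dtype=object)
        for f, (tr, te) in enumerate(plan):
            clf = RandomForestClassifier(
                n_estimators=settings.n_trees, max_depth=settings.max_depth,
                random_state=_derive_seed(config.rng_seed, 1, r, f), n_jobs=1)
            clf.fit(X[tr], y[tr])
            y_pred[te] = clf.predict(X[te])
        truths.append(y.copy())
        preds.append(y_pred)
    return aggregate_report(truths, preds, contrast[0],
                            repeats=config.cv_repeats, folds=config.cv_folds)


def rf_importance(
    table: PeakTable,
    contrast: tuple[str, str],
    settings: RfSettings,
    seed: int = 0,
    n_average: int = 10,
) -> list[ImportanceRecord]:
    """Normalized Gini importances from full-data forests.

    Averaged over ``n_average`` forest seeds (set 1 for single-seed mode);
    re-normalized to sum to one; ranking ties broken by metabolite name;
    zero-importance features are listed but flagged.
    """
    X, y = table.contrast_values(contrast)
    total = np.zeros(X.shape[1])
    for r in range(n_average):
        clf = RandomForestClassifier(
            n_estimators=settings.n_trees, max_depth=settings.max_depth,
            random_state=_derive_seed(seed, 2, r), n_jobs=1)
        clf.fit(X, y)
        total += clf.feature_importances_
    imp = total / n_average
    s = imp.sum()
    if s > 0:
        imp = imp / s
    names = table.metabolite_names
    order = sorted(range(len(names)), key=lambda j: (-imp[j], names[j]))
    return [
        ImportanceRecord(metabolite=names[j], importance=float(imp[j]),
                         rank=rank + 1, zero=bool(imp[j] == 0.0))
        for rank, j in enumerate(order)
    ]
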