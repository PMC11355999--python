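"""Pair-wise two-class PLS-DA with cross-validated R2, Q2 and accuracy.

The class response is a single centered +1/-1 column; features are
mean-centered (unit-variance scaling off by default).  Components are
extracted by the NIPALS algorithm with X-deflation (scikit-learn's
PLSRegression), so the one-component direction is proportional to the
class-mean difference on centered data.  Q2 = 1 - PRESS/TSS on held-out
samples under leave-one-out (default at these group sizes) or stratified
k-fold cross-validation; accuracy is the sign of the predicted response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .errors import ContrastError, MetaboPanelError, StageError
from .peaktable import PeakTable


@dataclass
class PlsdaModel:
    n_components: int
    x_weights: np.ndarray      # m x k
    x_loadings: np.ndarray     # m x k
    y_loadings: np.ndarray     # 1 x k
    scores: np.ndarray         # n x k
    r2x_cum: float
    r2y_cum: float
    q2_cum: float | None = None
    accuracy: float | None = None

    def summary(self) -> dict:
        return {
            "n_components": self.n_components,
            "r2x_cum": self.r2x_cum,
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
            "accuracy": self.accuracy,
        }


def _contrast_xy(table: PeakTable, contrast: tuple[str, str]):
    if table.stage != "log":
        raise StageError("PLS-DA expects a log-stage table")
    X, y = table.contrast_values(contrast)
    if len(np.unique(y)) < 2:
        raise ContrastError("PLS-DA needs two classes")
    return X, y.astype(float)


def fit_plsda(
    table: PeakTable,
    contrast: tuple[str, str],
    n_components: int = 5,
    scale: bool = False,
) -> PlsdaModel:
    """Fit a two-class PLS-DA model on the log-stage table."""
    X, y = _contrast_xy(table, contrast)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        raise MetaboPanelError(
            f"n_components={n_components} exceeds the data rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=scale)
    pls.fit(X, y)
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    # explained X variance from scores/loadings of the deflation
    ssx = (Xc ** 2).sum()
    r2x = float(((pls.x_scores_ @ pls.x_loadings_.T) ** 2).sum() / ssx)
    yhat = pls.predict(X).ravel()
    r2y = float(1.0 - ((y - yhat) ** 2).sum() / (yc ** 2).sum())
    return PlsdaModel(
        n_components=n_components,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        scores=pls.x_scores_,
        r2x_cum=r2x,
        r2y_cum=r2y,
    )


def cross_validate_plsda(
    table: PeakTable,
    contrast: tuple[str, str],
    n_components: int = 5,
    folds: int | None = None,
    seed: int = 0,
    scale: bool = False,
) -> tuple[float, float]:
    """Cross-validated (Q2, accuracy) for a two-class PLS-DA model.

    ``folds=None`` selects leave-one-out; otherwise stratified k-fold with
    shuffling driven by ``seed``.  Every training split must contain both
    classes.
    """
    X, y = _contrast_xy(table, contrast)
    if folds is None:
        splits = LeaveOneOut().split(X)
    else:
        if folds < 2:
            raise MetaboPanelError("folds must be >= 2")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(X, y)
    press = 0.0
    correct = 0
    n = len(y)
    for train, test in splits:
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            raise ContrastError("a CV training split lost one class")
        k = min(n_components, len(train) - 1, X.shape[1])
        pls = PLSRegression(n_components=k, scale=scale)
        pls.fit(X[train], ytr)
        pred = pls.predict(X[test]).ravel()
        press += float(((y[test] - pred) ** 2).sum())
        correct += int((np.sign(pred) == y[test]).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    return q2, correct / n


def run_plsda(
    table: PeakTable,
    contrast: tuple[str, str],
    n_components: int = 5,
    scale: bool = False,
    cv: str = "loo",
    folds: int = 3,
    seed: int = 0,
) -> PlsdaModel:
    """Fit plus cross-validated Q2/accuracy in one call."""
    model = fit_plsda(table, contrast, n_components, scale)
    q2, acc = cross_validate_plsda(
        table, contrast, n_components,
        folds=None if cv == "loo" else folds, seed=seed, scale=scale)
    model.q2_cum = q2
    model.accuracy = acc
    return model
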