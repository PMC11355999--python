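"""Classical univariate ROC marker analysis.

Per metabolite: empirical ROC curve over all thresholds, AUC (equal to the
Mann-Whitney U statistic divided by n1*n2, ties counting one half),
orientation so that reported AUC >= 0.5 with the "high" group recorded,
an optimal cutoff (closest point to the (0,1) corner by default, Youden J
switchable), and a stratified-bootstrap percentile 95 % confidence
interval.  Markers pass the gate when AUC is strictly above ``auc_gate``
(default 0.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .config import RunConfig
from .errors import ContrastError, StageError
from .peaktable import PeakTable


@dataclass
class MarkerResult:
    metabolite: str
    auc: float                      # post-orientation, in [0.5, 1]
    direction: str                  # group in which values are high
    cutoff: float                   # on the analyzed (log-stage) scale
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    ci95: tuple[float, float]
    passes_gate: bool
    fc: float = float("nan")
    fpr: np.ndarray | None = None   # ROC points for plotting
    tpr: np.ndarray | None = None


def _roc_points(values: np.ndarray, labels: np.ndarray):
    fpr, tpr, thr = roc_curve(labels, values, drop_intermediate=False)
    return fpr, tpr, thr


def _pick_cutoff(fpr, tpr, thr, criterion: str) -> int:
    finite = np.isfinite(thr)
    if criterion == "youden":
        score = tpr - fpr
        score[~finite] = -np.inf
        return int(np.argmax(score))
    dist = np.hypot(fpr, 1.0 - tpr)
    dist[~finite] = np.inf
    return int(np.argmin(dist))


def roc_auc(
    values,
    labels,
    positive: str = "positive",
    negative: str = "negative",
    metabolite: str = "",
    cutoff_criterion: str = "closest_topleft",
    auc_gate: float = 0.9,
) -> MarkerResult:
    """Empirical ROC/AUC for one variable against binary class labels.

    ``labels`` is boolean (True = positive class).  When the raw AUC is
    below 0.5 the orientation is flipped (values negated) and the reported
    direction becomes the negative class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise ContrastError("roc_auc needs >= 2 samples in each class")
    if np.allclose(values, values[0]):
        warnings.warn(f"constant values for {metabolite or 'variable'}; "
                      "AUC 0.5 with degenerate cutoff", stacklevel=2)
        return MarkerResult(metabolite, 0.5, positive, float(values[0]),
                            1.0, 0.0, (0.5, 0.5), False)
    fpr, tpr, thr = _roc_points(values, labels)
    raw_auc = float(_trapezoid_auc(fpr, tpr))
    direction = positive
    oriented = values
    if raw_auc < 0.5:
        # negating the scores maps AUC to 1 - raw; the positive class is
        # then the one with *low* values of the original variable
        direction = negative
        oriented = -values
        fpr, tpr, thr = _roc_points(oriented, labels)
    a = float(_trapezoid_auc(fpr, tpr))
    i = _pick_cutoff(fpr, tpr, thr.copy(), cutoff_criterion)
    cutoff = float(thr[i]) if direction == positive else float(-thr[i])
    return MarkerResult(
        metabolite=metabolite,
        auc=a,
        direction=direction,
        cutoff=cutoff,
        sensitivity_at_cutoff=float(tpr[i]),
        specificity_at_cutoff=float(1.0 - fpr[i]),
        ci95=(a, a),
        passes_gate=bool(a > auc_gate),
        fpr=fpr,
        tpr=tpr,
    )


def bootstrap_auc_ci(
    values,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the oriented AUC.

    Resampling within each class keeps both classes present in every
    resample; the orientation of the point estimate is reused so the
    interval refers to the reported (>= 0.5) AUC.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    point = roc_auc(values, labels)
    oriented = values if point.direction == "positive" else -values
    rng = np.random.default_rng(seed)
    pos = np.nonzero(labels)[0]
    neg = np.nonzero(~labels)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        v = np.concatenate([oriented[ip], oriented[ineg]])
        l = np.concatenate([np.ones(ip.size, bool), np.zeros(ineg.size, bool)])
        if np.allclose(v, v[0]):
            aucs[b] = 0.5
            continue
        fpr, tpr, _ = _roc_points(v, l)
        aucs[b] = _trapezoid_auc(fpr, tpr)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def screen_markers(
    table: PeakTable,
    contrast: tuple[str, str],
    config: RunConfig,
    tss_table: PeakTable | None = None,
    n_boot: int = 0,
    keep_curves: bool = False,
) -> list[MarkerResult]:
    """Per-metabolite ROC screen for one contrast.

    Output is sorted by AUC descending, then |log2 FC| descending (FC from
    ``tss_table`` when given), then name; the gate is strict
    (AUC > ``auc_gate``).  ``n_boot > 0`` adds bootstrap CIs.
    """
    if table.stage != "log":
        raise StageError("screen_markers expects a log-stage table")
    X, y = table.contrast_values(contrast)
    labels = y > 0
    fcs = {}
    if tss_table is not None:
        from .dem import fold_change
        fcs = {f.metabolite: f.fc for f in fold_change(tss_table, contrast)}
    results = []
    for j, met in enumerate(table.metabolites):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = roc_auc(X[:, j], labels, positive=contrast[0],
                        negative=contrast[1], metabolite=met.name,
                        cutoff_criterion=config.cutoff_criterion,
                        auc_gate=config.auc_gate)
        r.fc = fcs.get(met.name, float("nan"))
        if n_boot:
            r.ci95 = bootstrap_auc_ci(X[:, j], labels, n_boot=n_boot,
                                      seed=config.rng_seed + j)
        if not keep_curves:
            r.fpr = r.tpr = None
        results.append(r)

    def sort_key(r: MarkerResult):
        mag = abs(np.log2(r.fc)) if np.isfinite(r.fc) and r.fc > 0 else -1.0
        return (-r.auc, -mag, r.metabolite)

    return sorted(results, key=sort_key)
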