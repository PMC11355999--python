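"""QC-based drift normalization, QC quality gates, and TSS + log10 scaling.

Pooled-QC injections (equal aliquots of every study sample) are replicate
measurements of one material, so any trend in them over injection order is
instrumental drift.  For each metabolite a drift curve is fit to the pooled
QCs versus injection order — a least-squares line when four or fewer QCs
are available, otherwise a locally weighted (lowess) smoother — and every
sample's area is divided by the curve value at its own injection position,
then rescaled so the metabolite's median is unchanged.

Quality gates: a metabolite is kept when its residual pooled-QC coefficient
of variation is at most ``qc_cv_max`` percent and its pre-extraction
dilution series is linear in the dilution fraction with R^2 at least
``qc_linearity_r2_min``.

Statistical normalization is total sum scaling (each sample divided by its
total area, rows summing to 1) followed by log10, with half-minimum
substitution for zeros before logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import RunConfig
from .errors import InsufficientQcError, SchemaError, StageError
from .peaktable import PeakTable


@dataclass
class QcMetric:
    """Per-metabolite QC quality metrics."""

    metabolite: str
    cv_percent: float                 # residual pooled-QC CV after correction
    linearity_r2_pre: float           # pre-extraction dilution series
    linearity_r2_post: float          # post-extraction dilution series
    fit_degenerate: bool = False      # nonpositive drift factor; uncorrected
    kept: bool | None = None          # filled by qc_filter


@dataclass
class QcReport:
    metrics: list[QcMetric]
    drift_factors: np.ndarray         # samples x metabolites correction grid
    excluded: list[str] = field(default_factory=list)

    def metric(self, name: str) -> QcMetric:
        return next(m for m in self.metrics if m.metabolite == name)


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)


def _dilution_r2(fracs: np.ndarray, areas: np.ndarray) -> float:
    """R^2 of a straight-line fit of area against dilution fraction."""
    if fracs.size < 3 or np.ptp(fracs) == 0:
        return float("nan")
    if np.allclose(areas, areas[0]):
        return float("nan")
    r = stats.pearsonr(fracs, areas).statistic
    return float(r * r)


def qc_normalize(table: PeakTable) -> tuple[PeakTable, QcReport]:
    """Correct every metabolite for signal drift using the pooled QCs.

    Requires a raw-stage table with at least 2 pooled-QC injections.  A
    metabolite whose fitted curve would be nonpositive anywhere is flagged
    and left uncorrected.
    """
    if table.stage != "raw":
        raise StageError("qc_normalize expects a raw-stage table")
    qc_mask = table.role_mask("qc_pooled")
    n_qc = int(qc_mask.sum())
    if n_qc < 2:
        raise InsufficientQcError(
            f"need >= 2 pooled-QC injections for drift fitting, found {n_qc}")

    orders = np.array([s.injection_order for s in table.samples], dtype=float)
    qc_orders = orders[qc_mask]
    sort = np.argsort(qc_orders)
    qc_orders = qc_orders[sort]

    corrected = table.areas.copy()
    factors = np.ones_like(table.areas)
    metrics: list[QcMetric] = []

    dil_pre = np.array([s.role == "qc_dilution"
                        and s.dilution_stage == "pre_extraction"
                        for s in table.samples])
    dil_post = np.array([s.role == "qc_dilution"
                         and s.dilution_stage == "post_extraction"
                         for s in table.samples])
    fr_pre = np.array([s.dilution for s in table.samples])[dil_pre]
    fr_post = np.array([s.dilution for s in table.samples])[dil_post]

    for j, met in enumerate(table.metabolites):
        qc_y = table.areas[qc_mask, j][sort]
        if n_qc <= 4:
            slope, intercept = np.polyfit(qc_orders, qc_y, deg=1)
            curve_at = intercept + slope * orders
        else:
            sm = lowess(qc_y, qc_orders, frac=2.0 / 3.0, it=1,
                        return_sorted=True)
            curve_at = np.interp(orders, sm[:, 0], sm[:, 1])
        degenerate = bool(np.any(curve_at <= 0))
        if not degenerate:
            col = table.areas[:, j] / curve_at
            med_raw = np.median(table.areas[:, j])
            med_new = np.median(col)
            scale = med_raw / med_new if med_new > 0 else 1.0
            corrected[:, j] = col * scale
            factors[:, j] = curve_at / scale
        cv = _cv_percent(corrected[qc_mask, j])
        r2_pre = _dilution_r2(fr_pre, corrected[dil_pre, j])
        r2_post = _dilution_r2(fr_post, corrected[dil_post, j])
        metrics.append(QcMetric(met.name, cv, r2_pre, r2_post,
                                fit_degenerate=degenerate))

    out = table.advance(corrected, "qc_normalized")
    return out, QcReport(metrics=metrics, drift_factors=factors)


def qc_filter(table: PeakTable, report: QcReport,
              config: RunConfig) -> PeakTable:
    """Retain metabolites passing the CV and linearity gates.

    A metabolite with no dilution series (R^2 undefined) is judged on CV
    alone.  Excluded names are recorded on the report.
    """
    if len(report.metrics) != table.n_metabolites:
        raise SchemaError("QC report does not match table metabolites")
    keep_idx: list[int] = []
    report.excluded = []
    for j, m in enumerate(report.metrics):
        cv_ok = np.isfinite(m.cv_percent) and m.cv_percent <= config.qc_cv_max
        lin_ok = (not np.isfinite(m.linearity_r2_pre)
                  or m.linearity_r2_pre >= config.qc_linearity_r2_min)
        m.kept = bool(cv_ok and lin_ok)
        if m.kept:
            keep_idx.append(j)
        else:
            report.excluded.append(m.metabolite)
    return table.subset_metabolites(keep_idx)


def tss(table: PeakTable) -> PeakTable:
    """Total sum scaling: divide each sample by its total area."""
    if table.stage not in ("raw", "qc_normalized"):
        raise StageError("tss expects a raw or qc_normalized table")
    sums = table.areas.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        bad = [table.samples[i].sample_id for i in zero]
        raise SchemaError(f"samples with total area 0: {bad}")
    return table.advance(table.areas / sums[:, None], "tss")


def log_transform(table: PeakTable) -> PeakTable:
    """log10 with half-minimum substitution for zeros (per metabolite)."""
    if table.stage != "tss":
        raise StageError("log_transform expects a tss-stage table")
    areas = table.areas.copy()
    for j in range(areas.shape[1]):
        col = areas[:, j]
        if np.any(col == 0):
            positive = col[col > 0]
            if positive.size == 0:
                raise SchemaError(
                    f"metabolite {table.metabolites[j].name}: all areas zero")
            col[col == 0] = positive.min() / 2.0
    return table.advance(np.log10(areas), "log")


def tss_log(table: PeakTable) -> PeakTable:
    """TSS followed by log10 (the stage used by all downstream statistics)."""
    return log_transform(tss(table))
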