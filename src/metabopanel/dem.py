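"""Differentially expressed metabolite (DEM) calling.

Per metabolite, a two-sided two-sample t-test on log10 TSS values (Student
equal-variance by default, Welch switchable), Benjamini-Hochberg step-up
FDR adjustment across the retained metabolites of one contrast, and a
fold-change gate on the un-logged TSS group means.  A metabolite is a DEM
when the adjusted p-value is below ``fdr_alpha`` AND the fold change lies
outside the (``fc_down``, ``fc_up``) dead-band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .errors import ContrastError, MetaboPanelError, SchemaError, StageError
from .peaktable import PeakTable, contrast_name


class TtestResult(NamedTuple):
    metabolite: str
    p_value: float
    t_statistic: float


class FoldChange(NamedTuple):
    metabolite: str
    fc: float


@dataclass(frozen=True)
class DemRecord:
    """One row of a DEM table."""

    metabolite: str
    rt: float
    p_value: float
    p_adjusted: float
    fc: float
    is_dem: bool
    contrast: str


def ttest_per_metabolite(
    table: PeakTable,
    contrast: tuple[str, str],
    equal_var: bool = True,
) -> list[TtestResult]:
    """Two-sided two-sample t-test per metabolite on log-stage values.

    Degenerate case: zero within-group variance in both groups with equal
    means yields p = 1, t = 0 by convention.
    """
    if table.stage != "log":
        raise StageError("ttest_per_metabolite expects a log-stage table")
    a, b = contrast
    xa = table.areas[table.group_mask(a)]
    xb = table.areas[table.group_mask(b)]
    if len(xa) < 2 or len(xb) < 2:
        raise ContrastError(
            f"contrast {a} vs {b}: each group needs >= 2 samples")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # zero-variance columns are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(xa.mean(axis=0), xb.mean(axis=0))
    t[degenerate] = 0.0
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0  # zero variance, different means
    return [TtestResult(m.name, float(p[j]), float(t[j]))
            for j, m in enumerate(table.metabolites)]


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise MetaboPanelError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def fold_change(
    table: PeakTable, contrast: tuple[str, str]
) -> list[FoldChange]:
    """Ratio of group means (first-listed over second) on tss-stage areas."""
    if table.stage not in ("tss", "raw", "qc_normalized"):
        raise StageError("fold_change expects un-logged areas")
    a, b = contrast
    xa = table.areas[table.group_mask(a)]
    xb = table.areas[table.group_mask(b)]
    if len(xa) == 0 or len(xb) == 0:
        raise ContrastError(f"contrast {a} vs {b}: missing group")
    mean_a = xa.mean(axis=0)
    mean_b = xb.mean(axis=0)
    out = []
    for j, m in enumerate(table.metabolites):
        if mean_b[j] == 0:
            out.append(FoldChange(m.name, float("nan")))  # undefined, flagged
        else:
            out.append(FoldChange(m.name, float(mean_a[j] / mean_b[j])))
    return out


def call_dems(
    tests: Sequence[TtestResult],
    adjusted: Sequence[float],
    fcs: Sequence[FoldChange],
    config: RunConfig,
    contrast: tuple[str, str] | str = "",
    rt: Sequence[float] | None = None,
) -> list[DemRecord]:
    """Combine tests, BH-adjusted p and fold changes into DEM records.

    Records are sorted ascending by fold change (down-regulated block first,
    then up-regulated), mirroring the published table layout.
    """
    if not (len(tests) == len(adjusted) == len(fcs)):
        raise SchemaError("misaligned inputs to call_dems")
    for t, f in zip(tests, fcs):
        if t.metabolite != f.metabolite:
            raise SchemaError(
                f"misaligned metabolites: {t.metabolite!r} vs {f.metabolite!r}")
    cname = contrast if isinstance(contrast, str) else contrast_name(contrast)
    rts = list(rt) if rt is not None else [float("nan")] * len(tests)
    records = []
    for t, q, f, r in zip(tests, adjusted, fcs, rts):
        is_dem = bool(
            np.isfinite(f.fc)
            and q < config.fdr_alpha
            and (f.fc > config.fc_up or f.fc < config.fc_down))
        records.append(DemRecord(t.metabolite, r, t.p_value, float(q),
                                 f.fc, is_dem, cname))
    return sorted(records, key=lambda d: (not d.is_dem, d.fc))


def run_dem(
    log_table: PeakTable,
    tss_table: PeakTable,
    contrast: tuple[str, str],
    config: RunConfig,
) -> list[DemRecord]:
    """Full DEM calling for one contrast (t-test + BH + FC gate)."""
    tests = ttest_per_metabolite(log_table, contrast,
                                 equal_var=config.equal_var_ttest)
    q = bh_adjust([t.p_value for t in tests])
    # callers pass the raw-stage table here when config.fc_on_tss is False
    fcs = fold_change(tss_table, contrast)
    rts = [m.rt for m in log_table.metabolites]
    return call_dems(tests, q, fcs, config, contrast, rt=rts)
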