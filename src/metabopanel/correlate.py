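"""Metabolite-behavior correlation.

Pearson r between each metabolite's level (log10 TSS by default) and
week-6 forced-swim immobility time across all retained (non-excluded)
animals, pooled over groups.  The two-sided p-value comes from the exact
t-transform ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.
A correlation is significant when |r| strictly exceeds
``correlation_r_min`` (default 0.4) and p is strictly below
``correlation_p_max`` (default 0.05); no multiplicity correction enters
the gate, but a Benjamini-Hochberg column is emitted for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import RunConfig
from .dem import bh_adjust
from .errors import SchemaError, StageError
from .peaktable import PeakTable
from .phenotype import FstRecord, PhenotypeLabel


@dataclass
class CorrelationRecord:
    metabolite: str
    r: float
    p_value: float
    significant: bool
    p_bh: float = float("nan")
    flagged: bool = False       # undefined r (constant input)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t-transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_behavior(
    table: PeakTable,
    behavior: Sequence[FstRecord],
    labels: Sequence[PhenotypeLabel],
    config: RunConfig,
) -> list[CorrelationRecord]:
    """Per-metabolite Pearson correlation with week-6 immobility.

    Only retained animals enter; every retained sample must match a
    behavior record.  Output is sorted ascending by r.
    """
    if config.correlation_scale == "log":
        if table.stage != "log":
            raise StageError("correlate_behavior expects a log-stage table")
    excluded = {l.animal_id for l in labels if l.excluded}
    imm6 = {r.animal_id: r.immobility[2] for r in behavior}
    rows, y = [], []
    for i, s in enumerate(table.samples):
        if s.role != "study" or s.sample_id in excluded:
            continue
        if s.sample_id not in imm6:
            raise SchemaError(
                f"sample {s.sample_id!r} has no behavior record")
        rows.append(i)
        y.append(imm6[s.sample_id])
    if len(rows) < 3:
        raise SchemaError("need >= 3 retained animals for correlation")
    X = table.areas[rows]
    y = np.asarray(y, dtype=float)
    n = len(y)
    records = []
    ps = []
    for j, met in enumerate(table.metabolites):
        x = X[:, j]
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            records.append(CorrelationRecord(met.name, float("nan"),
                                             float("nan"), False,
                                             flagged=True))
            ps.append(1.0)
            continue
        r = float(stats.pearsonr(x, y).statistic)
        p = pearson_p_from_r(r, n)
        sig = bool(abs(r) > config.correlation_r_min
                   and p < config.correlation_p_max)
        records.append(CorrelationRecord(met.name, r, p, sig))
        ps.append(p)
    qs = bh_adjust(ps)
    for rec, q in zip(records, qs):
        rec.p_bh = float("nan") if rec.flagged else float(q)
    return sorted(records,
                  key=lambda r: (np.inf if np.isnan(r.r) else r.r))
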