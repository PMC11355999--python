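"""Full-study orchestration.

``run_study`` composes the whole analysis: simulate (or read) the peak and
behavior tables, phenotype the animals and drop excluded ones, QC-normalize
and filter, TSS + log scale, then run DEM calling, PLS-DA, ROC marker
screening, SVM forward selection and random-forest classification for each
of the three study contrasts (Control+Flx vs Control, CSIS vs Control,
CSIS+Flx vs CSIS), and finally the pooled metabolite-immobility
correlation.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as mio
from .config import RunConfig
from .correlate import CorrelationRecord, correlate_behavior
from .dem import DemRecord, run_dem
from .errors import ContrastError
from .peaktable import DEFAULT_CONTRASTS, PeakTable, contrast_name
from .phenotype import FstRecord, PhenotypeLabel, phenotype_cohort
from .plsda import run_plsda
from .preprocess import QcReport, log_transform, qc_filter, qc_normalize, tss
from .rf import (ImportanceRecord, RfSettings, evaluate_rf, rf_importance,
                 tune_rf_oob)
from .roc import MarkerResult, screen_markers
from .simulate import GroundTruth, SimDesign, simulate_behavior, \
    simulate_peak_table
from .svm import ClassifierReport, SelectionPath, greedy_forward_select


@dataclass
class ContrastResult:
    contrast: str
    dems: list[DemRecord]
    plsda_summary: dict
    markers: list[MarkerResult]
    svm_path: SelectionPath | None
    svm_report: ClassifierReport | None
    rf_settings: RfSettings | None
    rf_report: ClassifierReport | None
    rf_importances: list[ImportanceRecord]


@dataclass
class StudyReport:
    config: RunConfig
    labels: list[PhenotypeLabel]
    qc_report: QcReport
    contrasts: dict[str, ContrastResult]
    correlations: list[CorrelationRecord]
    truth: GroundTruth | None = None
    n_metabolites_raw: int = 0
    n_metabolites_kept: int = 0

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot serialize {type(o)}")

        payload = {
            "config": self.config.to_dict(),
            "labels": [dataclasses.asdict(l) for l in self.labels],
            "n_metabolites_raw": self.n_metabolites_raw,
            "n_metabolites_kept": self.n_metabolites_kept,
            "qc_excluded": self.qc_report.excluded if self.qc_report else [],
            "contrasts": {
                c: {
                    "dems": [dataclasses.asdict(d) for d in r.dems],
                    "plsda": r.plsda_summary,
                    "markers": [
                        {"metabolite": m.metabolite, "auc": m.auc,
                         "fc": m.fc, "direction": m.direction,
                         "cutoff": m.cutoff,
                         "sensitivity": m.sensitivity_at_cutoff,
                         "specificity": m.specificity_at_cutoff,
                         "ci95": list(m.ci95),
                         "passes_gate": m.passes_gate}
                        for m in r.markers],
                    "svm_path": ([{"metabolite": n, "mean_cv_accuracy": a}
                                  for n, a in r.svm_path.steps]
                                 if r.svm_path else None),
                    "svm_panel": r.svm_path.panel if r.svm_path else None,
                    "svm_report": (r.svm_report.to_dict()
                                   if r.svm_report else None),
                    "rf_settings": (
                        {"n_trees": r.rf_settings.n_trees,
                         "max_depth": r.rf_settings.max_depth,
                         "oob_score": r.rf_settings.oob_score}
                        if r.rf_settings else None),
                    "rf_report": (r.rf_report.to_dict()
                                  if r.rf_report else None),
                    "rf_importances": [dataclasses.asdict(i)
                                       for i in r.rf_importances],
                }
                for c, r in self.contrasts.items()
            },
            "correlations": [dataclasses.asdict(c)
                             for c in self.correlations],
        }
        return json.dumps(payload, indent=1, default=enc)


def run_study(
    config: RunConfig,
    design: SimDesign | None = None,
    peak_table: PeakTable | None = None,
    behavior: Sequence[FstRecord] | None = None,
    out_dir: str | Path | None = None,
    contrasts=DEFAULT_CONTRASTS,
    run_svm: bool = True,
    run_rf: bool = True,
    n_boot: int = 0,
) -> StudyReport:
    """Run the complete study on simulated or supplied data."""
    truth = None
    if peak_table is None:
        design = design or SimDesign()
        peak_table, truth = simulate_peak_table(design, config.rng_seed)
        behavior = simulate_behavior(design, peak_table, truth,
                                     config.rng_seed)
    if behavior is None:
        raise ValueError("behavior records are required")

    labels = phenotype_cohort(
        behavior,
        increase_pct=config.immobility_increase_pct,
        decrease_pct=config.immobility_decrease_pct)
    excluded = {l.animal_id for l in labels if l.excluded}
    keep = [i for i, s in enumerate(peak_table.samples)
            if s.sample_id not in excluded]
    table = peak_table.subset_samples(keep)

    n_raw = table.n_metabolites
    if table.role_mask("qc_pooled").sum() >= 2:
        normalized, qc_report = qc_normalize(table)
        filtered = qc_filter(normalized, qc_report, config)
    else:
        normalized, qc_report = table, QcReport(metrics=[], drift_factors=
                                                np.ones_like(table.areas))
        filtered = normalized
    tss_table = tss(filtered)
    log_table = log_transform(tss_table)

    results: dict[str, ContrastResult] = {}
    for contrast in contrasts:
        cname = contrast_name(contrast)
        try:
            dems = run_dem(log_table, tss_table, contrast, config)
            n_class = min(log_table.contrast_values(contrast)[1].size, 10)
            k = min(5, n_class - 2, log_table.n_metabolites)
            pls = run_plsda(log_table, contrast, n_components=max(k, 1),
                            scale=config.plsda_scale, cv=config.plsda_cv,
                            folds=config.cv_folds, seed=config.rng_seed)
            markers = screen_markers(log_table, contrast, config,
                                     tss_table=tss_table, n_boot=n_boot)
        except ContrastError:
            continue
        svm_path = svm_report = rf_settings = rf_report = None
        rf_imps: list[ImportanceRecord] = []
        if run_svm:
            svm_path, svm_report = greedy_forward_select(
                log_table, contrast, config)
        if run_rf:
            rf_settings = tune_rf_oob(log_table, contrast,
                                      seed=config.rng_seed)
            rf_report = evaluate_rf(log_table, contrast, rf_settings, config)
            rf_imps = rf_importance(log_table, contrast, rf_settings,
                                    seed=config.rng_seed,
                                    n_average=config.cv_repeats)
        results[cname] = ContrastResult(
            contrast=cname, dems=dems, plsda_summary=pls.summary(),
            markers=markers, svm_path=svm_path, svm_report=svm_report,
            rf_settings=rf_settings, rf_report=rf_report,
            rf_importances=rf_imps)

    correlations = correlate_behavior(
        log_table if config.correlation_scale == "log" else table,
        behavior, labels, config)

    report = StudyReport(
        config=config, labels=labels, qc_report=qc_report,
        contrasts=results, correlations=correlations, truth=truth,
        n_metabolites_raw=n_raw, n_metabolites_kept=filtered.n_metabolites)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mio.write_peak_table(peak_table, out_dir / "peak_table.csv")
        mio.write_behavior_table(behavior, out_dir / "behavior.csv")
        artifacts = {"phenotype": labels, "correlation": correlations}
        for cname, r in results.items():
            artifacts[f"dem_{cname}"] = r.dems
            artifacts[f"markers_{cname}"] = r.markers
            if r.rf_importances:
                artifacts[f"importance_{cname}"] = r.rf_importances
        mio.write_result_tables(
            {k: v for k, v in artifacts.items() if v}, out_dir)
        (out_dir / "study_report.json").write_text(report.to_json())
        if truth is not None:
            (out_dir / "ground_truth.json").write_text(truth.to_json())
    return report


def compare_panels(report: StudyReport) -> dict:
    """Set overlaps of marker lists and SVM panels across contrasts."""
    markers = {
        c: {m.metabolite for m in r.markers if m.passes_gate}
        for c, r in report.contrasts.items()
    }
    panels = {
        c: set(r.svm_path.panel) if r.svm_path else set()
        for c, r in report.contrasts.items()
    }
    out: dict[str, dict] = {"markers": {}, "svm_panels": {}}
    names = list(report.contrasts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            key = f"{a} & {b}"
            out["markers"][key] = {
                "overlap": sorted(markers[a] & markers[b]),
                "count": len(markers[a] & markers[b]),
                "only_first": sorted(markers[a] - markers[b]),
                "only_second": sorted(markers[b] - markers[a]),
            }
            out["svm_panels"][key] = {
                "overlap": sorted(panels[a] & panels[b]),
                "count": len(panels[a] & panels[b]),
            }
    return out
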