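"""Synthetic study generator with known ground truth.

Emulates the structure of an untargeted LC-MS serum metabolomics study of
chronically socially isolated (CSIS) rats with and without fluoxetine:
four study groups (Control 6, CSIS 6, Control+Flx 8, CSIS+Flx 8 animals),
~101 annotated metabolites with log-normal peak areas, a planted set of
differential metabolites per contrast, pooled-QC injections carrying a
smooth multiplicative signal drift over the run, pre-/post-extraction
dilution series at relative concentrations 1/0.8/0.5/0.2/0.1, near-zero
blanks, and forced-swim immobility trajectories coupled to a subset of the
planted metabolites.

Model: metabolite ``j`` in group ``g`` is drawn as
``area = exp(mu_j + delta_{gj} + eps)``, ``eps ~ N(0, sigma_b)``, with
``sigma_b = sqrt(ln(1 + cv_within^2))`` so that ``cv_within`` is the
biological coefficient of variation on the natural scale and the planted
log-offset ``delta`` makes the *ratio of group means* equal the planted
fold change exactly in the population.  Technical noise is multiplicative
log-normal with ``cv_technical``; drift is a half-cosine multiplicative
trend in injection order applied to every injection.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DesignError, SchemaError
from .peaktable import (DEFAULT_CONTRASTS, GROUPS, Metabolite, PeakTable,
                        SampleMeta, contrast_name)
from .phenotype import FstRecord


def _default_groups() -> dict[str, int]:
    return {"Control": 6, "CSIS": 6, "ControlFlx": 8, "CSISFlx": 8}


def _default_planted() -> dict[str, int]:
    # counts of differential metabolites per contrast, as in the study design
    return {"ControlFlx:Control": 13, "CSIS:Control": 3, "CSISFlx:CSIS": 9}


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic study."""

    n_per_group: Mapping[str, int] = field(default_factory=_default_groups)
    n_metabolites: int = 101
    n_planted: Mapping[str, int] = field(default_factory=_default_planted)
    fc_down_range: tuple[float, float] = (0.30, 0.35)
    fc_up_range: tuple[float, float] = (1.25, 3.3)
    frac_down: float = 0.5             # share of planted effects pointing down
    base_log_mean_range: tuple[float, float] = (4.0, 7.0)  # log10 abundance
    cv_within: float = 0.2             # biological CV (natural scale)
    cv_technical: float = 0.05         # QC replicate CV
    drift_amplitude: float = 0.2       # multiplicative drift over the run
    n_qc: int = 6                      # pooled-QC injections
    dilution_fractions: tuple[float, ...] = (1.0, 0.8, 0.5, 0.2, 0.1)
    n_blank: int = 2
    # behavior
    behavior_coupling: Mapping[int, float] | None = None  # index -> s per SD
    default_coupling_strength: float = 25.0
    noise_sd_behavior: float = 8.0     # seconds, test-retest noise
    animal_trait_sd: float = 0.18      # log-scale animal random effect
    baseline_immobility: tuple[float, float] = (100.0, 15.0)  # mean, sd
    csis_week3_factor: float = 1.6
    csis_week6_factor: float = 1.7
    flx_week6_factor: float = 0.55     # applied to the animal's week-3 value
    resilient_fraction: float = 0.0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise DesignError(f"unknown group {g!r}")
            if n < 2:
                raise DesignError(f"group {g}: at least 2 animals required")
        total_planted = sum(self.n_planted.values())
        if total_planted > self.n_metabolites:
            raise DesignError(
                f"planted metabolites ({total_planted}) exceed "
                f"n_metabolites ({self.n_metabolites})")
        if not (self.fc_down_range[1] < 1 < self.fc_up_range[0]):
            raise DesignError("planted fold changes must straddle 1 from "
                              "outside the dead-band")
        if self.n_qc < 0 or self.n_metabolites < 1:
            raise DesignError("n_qc >= 0 and n_metabolites >= 1 required")

    def replace(self, **kwargs) -> "SimDesign":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects: per-contrast {metabolite index: true FC} and
    behavior couplings {metabolite index: seconds per SD of log10 area}."""

    planted: Mapping[str, Mapping[int, float]]
    coupled: Mapping[int, float]

    def to_json(self) -> str:
        return json.dumps({
            "planted": {c: {str(k): v for k, v in d.items()}
                        for c, d in self.planted.items()},
            "coupled": {str(k): v for k, v in self.coupled.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(
            planted={c: {int(k): float(v) for k, v in d.items()}
                     for c, d in data["planted"].items()},
            coupled={int(k): float(v) for k, v in data["coupled"].items()},
        )


def _drift(order: np.ndarray, n_total: int, amplitude: float) -> np.ndarray:
    """Half-cosine multiplicative trend: 1 at injection 1, 1+A at the end."""
    if n_total <= 1 or amplitude == 0:
        return np.ones_like(order, dtype=float)
    u = (order - 1) / (n_total - 1)
    return 1.0 + amplitude * 0.5 * (1.0 - np.cos(np.pi * u))


def simulate_peak_table(
    design: SimDesign, seed: int
) -> tuple[PeakTable, GroundTruth]:
    """Draw one synthetic peak table; identical seed gives identical output."""
    root = np.random.SeedSequence(seed)
    ss_table, _ = root.spawn(2)
    rng = np.random.default_rng(ss_table)

    m = design.n_metabolites
    mu10 = rng.uniform(*design.base_log_mean_range, size=m)
    mu = mu10 * np.log(10.0)                       # natural-log means
    sigma_b = np.sqrt(np.log1p(design.cv_within ** 2))
    sigma_t = np.sqrt(np.log1p(design.cv_technical ** 2))

    # plant fold changes: disjoint primary metabolite sets across contrasts.
    # Planting is restricted to the sub-dominant abundance range (lower half
    # of the per-metabolite means, extended only if the design demands more)
    # so that planted mass changes stay small relative to the total ion
    # current: total-sum scaling then leaves unplanted metabolites inside
    # the fold-change dead-band instead of dragging them down with the
    # compositional closure.
    total_planted = sum(design.n_planted.values())
    pool_size = max(total_planted, m // 2) if m > 1 else m
    by_abundance = np.argsort(mu10, kind="stable")
    pool = by_abundance[:pool_size]
    order = pool[rng.permutation(pool_size)]
    offsets = {g: np.zeros(m) for g in design.n_per_group}
    pos = 0
    for contrast in DEFAULT_CONTRASTS:
        cname = contrast_name(contrast)
        k = design.n_planted.get(cname, 0)
        idx = order[pos:pos + k]
        pos += k
        for j in idx:
            if rng.random() < design.frac_down:
                lo, hi = design.fc_down_range
            else:
                lo, hi = design.fc_up_range
            fc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            # shift the first-listed group relative to the second
            offsets[contrast[0]][j] += np.log(fc)

    # ground truth records the *effective* FC of every contrast: a shift
    # planted on the CSIS group also makes that metabolite differential in
    # the CSISFlx vs CSIS comparison (the treated group is not shifted),
    # mirroring treatment-normalized stress metabolites
    planted: dict[str, dict[int, float]] = {}
    for contrast in DEFAULT_CONTRASTS:
        a, b = contrast
        delta = offsets.get(a, np.zeros(m)) - offsets.get(b, np.zeros(m))
        planted[contrast_name(contrast)] = {
            int(j): float(np.exp(delta[j]))
            for j in np.nonzero(delta != 0.0)[0]
        }

    # behavior couplings: by default one up-regulated stress metabolite
    # couples positively and one up-regulated treatment metabolite negatively
    if design.behavior_coupling is not None:
        coupled = {int(k): float(v)
                   for k, v in design.behavior_coupling.items()}
    else:
        coupled = {}
        s = design.default_coupling_strength
        up_csis = [j for j, fc in planted.get("CSIS:Control", {}).items()
                   if fc > 1]
        up_flx = [j for j, fc in planted.get("CSISFlx:CSIS", {}).items()
                  if fc > 1]
        if up_csis:
            coupled[min(up_csis)] = +s
        if up_flx:
            coupled[min(up_flx)] = -s

    # ---- assemble injections ---------------------------------------------
    samples: list[SampleMeta] = []
    rows: list[np.ndarray] = []

    study_meta: list[tuple[str, str]] = []   # (sample_id, group)
    for g in ("Control", "ControlFlx", "CSIS", "CSISFlx"):
        for i in range(design.n_per_group.get(g, 0)):
            study_meta.append((f"{g}_{i + 1:02d}", g))
    study_perm = rng.permutation(len(study_meta))

    n_dilution = (len(design.dilution_fractions)
                  + max(len(design.dilution_fractions) - 1, 0))
    n_total = (design.n_blank + n_dilution + design.n_qc + len(study_meta))

    # population mean area per metabolite across study samples (pre-drift)
    group_means = np.array([
        np.exp(mu + offsets[g] + 0.5 * sigma_b ** 2)
        for _, g in study_meta
    ])
    pooled_mean = group_means.mean(axis=0)

    injection = 1

    def tech_noise() -> np.ndarray:
        return np.exp(rng.normal(0.0, sigma_t, size=m))

    # blanks first
    for b in range(design.n_blank):
        d = _drift(np.array([injection]), n_total, design.drift_amplitude)[0]
        rows.append(pooled_mean * 1e-4 * tech_noise() * d)
        samples.append(SampleMeta(f"Blank_{b + 1}", "QC", role="blank",
                                  injection_order=injection))
        injection += 1
    # dilution series: pre-extraction (includes the undiluted point), then
    # post-extraction re-dilutions of the undiluted QC
    for stage_tag, fracs in (
        ("pre_extraction", design.dilution_fractions),
        ("post_extraction", design.dilution_fractions[1:]),
    ):
        for f in fracs:
            d = _drift(np.array([injection]), n_total,
                       design.drift_amplitude)[0]
            rows.append(pooled_mean * f * tech_noise() * d)
            samples.append(SampleMeta(
                f"QCdil_{stage_tag[:3]}_{f:g}", "QC", role="qc_dilution",
                dilution=f, dilution_stage=stage_tag,
                injection_order=injection))
            injection += 1

    # pooled QCs spread evenly through the remaining run
    remaining = design.n_qc + len(study_meta)
    qc_slots = set()
    if design.n_qc > 0:
        slots = np.linspace(0, remaining - 1, design.n_qc).round().astype(int)
        qc_slots = set(int(s) for s in slots)
    study_iter = iter(study_perm)
    qc_count = 0
    study_rows: dict[str, np.ndarray] = {}
    for slot in range(remaining):
        d = _drift(np.array([injection]), n_total, design.drift_amplitude)[0]
        if slot in qc_slots:
            qc_count += 1
            rows.append(pooled_mean * tech_noise() * d)
            samples.append(SampleMeta(f"QCpool_{qc_count}", "QC",
                                      role="qc_pooled",
                                      injection_order=injection))
        else:
            sid, g = study_meta[next(study_iter)]
            area = np.exp(mu + offsets[g]
                          + rng.normal(0.0, sigma_b, size=m)) * d
            rows.append(area)
            study_rows[sid] = area
            samples.append(SampleMeta(sid, g, injection_order=injection))
        injection += 1

    metabolites = [Metabolite(f"M{j + 1:03d}",
                              rt=round(float(rng.uniform(1.0, 20.0)), 2),
                              mz=round(float(rng.uniform(70.0, 500.0)), 4))
                   for j in range(m)]
    table = PeakTable(samples, metabolites, np.vstack(rows), stage="raw")
    return table, GroundTruth(planted=planted, coupled=coupled)


def simulate_behavior(
    design: SimDesign,
    table: PeakTable,
    truth: GroundTruth,
    seed: int,
) -> list[FstRecord]:
    """Draw FST trajectories coupled to the planted metabolites.

    Week-6 immobility receives an additive contribution
    ``beta_k * z_k`` (seconds) per coupled metabolite, where ``z_k`` is the
    across-study-samples z-score of log10 area, so the population Pearson
    correlation carries the designed sign.  Times are clipped to [0, 300] s.
    """
    if table.stage != "raw":
        raise SchemaError("behavior simulation expects a raw-stage table")
    root = np.random.SeedSequence(seed)
    _, ss_beh = root.spawn(2)
    rng = np.random.default_rng(ss_beh)

    study_idx = np.nonzero(table.study_mask)[0]
    if study_idx.size == 0:
        raise SchemaError("no study samples in table")
    log_areas = np.log10(table.areas[study_idx])
    z = (log_areas - log_areas.mean(axis=0)) / (log_areas.std(axis=0) + 1e-12)

    mean0, sd0 = design.baseline_immobility
    records: list[FstRecord] = []
    for row, si in enumerate(study_idx):
        s = table.samples[si]
        base = float(np.clip(rng.normal(mean0, sd0), 20.0, 250.0))
        trait = np.exp(rng.normal(0.0, design.animal_trait_sd, size=2))
        resilient = (s.group in ("CSIS", "CSISFlx")
                     and rng.random() < design.resilient_fraction)
        if s.group in ("Control", "ControlFlx"):
            wk3 = base * trait[0]
            wk6 = base * trait[1]
        elif resilient:
            wk3 = base * trait[0]            # no stress response
            wk6 = base * trait[1]
        elif s.group == "CSIS":
            wk3 = base * design.csis_week3_factor * trait[0]
            wk6 = base * design.csis_week6_factor * trait[1]
        else:  # CSISFlx: stressed by week 3, treated response by week 6
            wk3 = base * design.csis_week3_factor * trait[0]
            wk6 = wk3 * design.flx_week6_factor * trait[1] / trait[0]
        wk3 += rng.normal(0.0, design.noise_sd_behavior)
        wk6 += rng.normal(0.0, design.noise_sd_behavior)
        for k, beta in truth.coupled.items():
            wk6 += beta * z[row, k]
        imm = np.clip([base, wk3, wk6], 0.0, 300.0)
        swim = np.clip((300.0 - imm) * 0.7, 0.0, None)
        climb = np.clip((300.0 - imm) * 0.25, 0.0, None)
        records.append(FstRecord(
            animal_id=s.sample_id, arm=s.group,
            immobility=tuple(float(v) for v in imm),
            swimming=tuple(float(v) for v in swim),
            climbing=tuple(float(v) for v in climb),
        ))
    return records
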