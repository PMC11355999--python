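"""Phenotype classification from forced-swim-test (FST) trajectories.

Animals are tested at weeks 0 (baseline), 3 and 6; immobility time (s)
within the 5-minute test stage is the despair readout.  The rules, all with
strict percentage thresholds:

* an isolation-reared animal is *CSIS* (stress-responsive) when immobility
  rose by more than 20 % over baseline at week 3 AND week 6;
* a fluoxetine-treated isolated animal must first meet the week-3 criterion,
  and is a *responder* when week-6 immobility fell by more than 20 %
  relative to its own week-3 value OR to the untreated-CSIS reference at
  week 6 (the wording admits both readings, so the disjunction is applied
  and the branch that fired is recorded in the rationale);
* animals failing these rules are *resilient* and excluded from all
  downstream statistics;
* Control and Control+Flx animals are labelled without thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SchemaError

LABELS = ("control", "control_flx", "csis", "flx_responder",
          "csis_resilient_excluded", "flx_resilient_excluded")
EXCLUDED_LABELS = ("csis_resilient_excluded", "flx_resilient_excluded")


@dataclass(frozen=True)
class FstRecord:
    """One animal's FST trajectory: times (s) at weeks 0, 3, 6."""

    animal_id: str
    arm: str                               # Control/ControlFlx/CSIS/CSISFlx
    immobility: tuple[float, float, float]
    swimming: tuple[float, float, float] = (0.0, 0.0, 0.0)
    climbing: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for week in range(3):
            i, s, c = (self.immobility[week], self.swimming[week],
                       self.climbing[week])
            if min(i, s, c) < 0:
                raise SchemaError(
                    f"animal {self.animal_id}: negative time at week index "
                    f"{week}")
            if i + s + c > 300.0 + 1e-9:
                raise SchemaError(
                    f"animal {self.animal_id}: times exceed the 300 s test "
                    f"stage at week index {week}")


@dataclass(frozen=True)
class PhenotypeLabel:
    animal_id: str
    label: str
    rationale: str

    @property
    def excluded(self) -> bool:
        return self.label in EXCLUDED_LABELS


def _pct_change(now: float, ref: float) -> float:
    return 100.0 * (now - ref) / ref


def classify_csis(record: FstRecord,
                  increase_pct: float = 20.0) -> PhenotypeLabel:
    """Apply the stress-response criterion to a CSIS or CSIS+Flx animal.

    For the CSIS arm both week-3 and week-6 immobility must exceed baseline
    by strictly more than ``increase_pct``; for the CSIS+Flx arm only the
    week-3 condition is assessed here (week 6 belongs to the responder
    rule), and the label ``csis`` then means "eligible for responder
    assessment".
    """
    if record.arm not in ("CSIS", "CSISFlx"):
        raise ValueError(f"classify_csis applies to CSIS arms, got "
                         f"{record.arm!r}")
    base, wk3, wk6 = record.immobility
    if base == 0:
        raise ZeroDivisionError(
            f"animal {record.animal_id}: baseline immobility is 0; percent "
            "change undefined")
    d3, d6 = _pct_change(wk3, base), _pct_change(wk6, base)
    if record.arm == "CSIS":
        if d3 > increase_pct and d6 > increase_pct:
            return PhenotypeLabel(
                record.animal_id, "csis",
                f"week3 +{d3:.1f}% and week6 +{d6:.1f}% both > "
                f"{increase_pct:g}% over baseline")
        return PhenotypeLabel(
            record.animal_id, "csis_resilient_excluded",
            f"week3 {d3:+.1f}% / week6 {d6:+.1f}% vs baseline; both must "
            f"exceed +{increase_pct:g}%")
    # CSISFlx: eligibility via the week-3 criterion only
    if d3 > increase_pct:
        return PhenotypeLabel(
            record.animal_id, "csis",
            f"week3 +{d3:.1f}% > {increase_pct:g}% over baseline; "
            "eligible for responder assessment")
    return PhenotypeLabel(
        record.animal_id, "csis_resilient_excluded",
        f"week3 {d3:+.1f}% vs baseline does not exceed +{increase_pct:g}%")


def classify_responder(
    record: FstRecord,
    csis_reference: tuple[float, float],
    decrease_pct: float = 20.0,
) -> PhenotypeLabel:
    """Apply the fluoxetine-response rule to a CSIS+Flx animal.

    ``csis_reference`` carries the untreated-CSIS group's (week-3, week-6)
    mean immobility.  The animal responds when its week-6 immobility is
    strictly below ``(1 - decrease_pct/100)`` times its own week-3 value OR
    the reference week-6 value.
    """
    if record.arm != "CSISFlx":
        raise ValueError("classify_responder applies to CSISFlx animals")
    _, wk3, wk6 = record.immobility
    if not np.isfinite(wk3):
        raise SchemaError(f"animal {record.animal_id}: missing week-3 value")
    frac = 1.0 - decrease_pct / 100.0
    own = wk6 < frac * wk3
    ref = wk6 < frac * csis_reference[1]
    if own or ref:
        branch = "own week-3" if own else "CSIS group week-6"
        return PhenotypeLabel(
            record.animal_id, "flx_responder",
            f"week6 {wk6:.1f}s < {100 - decrease_pct:g}% of {branch} "
            f"reference")
    return PhenotypeLabel(
        record.animal_id, "flx_resilient_excluded",
        f"week6 {wk6:.1f}s >= {100 - decrease_pct:g}% of both week-3 "
        f"({frac * wk3:.1f}s) and CSIS week-6 ({frac * csis_reference[1]:.1f}s)"
        " references")


def phenotype_cohort(
    records: Sequence[FstRecord],
    increase_pct: float = 20.0,
    decrease_pct: float = 20.0,
) -> list[PhenotypeLabel]:
    """Label every animal with the arm-appropriate rule.

    The untreated-CSIS reference for the responder rule is the mean
    week-3/week-6 immobility of CSIS-arm animals meeting the stress
    criterion (falling back to the whole CSIS arm when none do).
    """
    if not records:
        raise ValueError("empty cohort")
    csis_arm = [r for r in records if r.arm == "CSIS"]
    responsive = [r for r in csis_arm
                  if classify_csis(r, increase_pct).label == "csis"]
    ref_pool = responsive or csis_arm
    if ref_pool:
        ref = (float(np.mean([r.immobility[1] for r in ref_pool])),
               float(np.mean([r.immobility[2] for r in ref_pool])))
    else:
        ref = (np.inf, np.inf)  # no CSIS arm: only the own-week-3 branch

    labels: list[PhenotypeLabel] = []
    for r in records:
        if r.arm == "Control":
            labels.append(PhenotypeLabel(r.animal_id, "control",
                                         "control arm; no thresholding"))
        elif r.arm == "ControlFlx":
            labels.append(PhenotypeLabel(r.animal_id, "control_flx",
                                         "treated-control arm; no "
                                         "thresholding"))
        elif r.arm == "CSIS":
            labels.append(classify_csis(r, increase_pct))
        else:  # CSISFlx
            eligibility = classify_csis(r, increase_pct)
            if eligibility.label != "csis":
                labels.append(eligibility)
            else:
                labels.append(classify_responder(r, ref, decrease_pct))
    return labels


def retained_ids(labels: Sequence[PhenotypeLabel]) -> list[str]:
    return [l.animal_id for l in labels if not l.excluded]
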