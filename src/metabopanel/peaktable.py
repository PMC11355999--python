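"""The samples x metabolites peak-area container and its processing stages.

A :class:`PeakTable` holds a nonnegative area matrix (one row per injected
sample, one column per annotated metabolite) together with per-sample
metadata (study group, QC role, dilution, injection order) and per-metabolite
annotation (name, retention time, m/z).  The ``stage`` tag enforces the
processing order raw -> qc_normalized -> tss -> log; transitions outside
that order raise :class:`~metabopanel.errors.StageError` (a raw table may
skip straight to tss when no pooled QCs exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContrastError, SchemaError, StageError

GROUPS = ("Control", "ControlFlx", "CSIS", "CSISFlx")
ROLES = ("study", "qc_pooled", "qc_dilution", "blank")
STAGES = ("raw", "qc_normalized", "tss", "log")
DILUTION_STAGES = ("pre_extraction", "post_extraction", "none")

#: the three ordered contrasts of the study design (first-listed = positive)
DEFAULT_CONTRASTS = (
    ("ControlFlx", "Control"),
    ("CSIS", "Control"),
    ("CSISFlx", "CSIS"),
)

_ALLOWED_TRANSITIONS = {
    ("raw", "qc_normalized"),
    ("raw", "tss"),
    ("qc_normalized", "tss"),
    ("tss", "log"),
}


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one injected sample."""

    sample_id: str
    group: str                      # study group, or "QC" for QC/blank rows
    role: str = "study"
    dilution: float = 1.0
    dilution_stage: str = "none"
    injection_order: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown sample role {self.role!r}")
        if self.role == "study" and self.group not in GROUPS:
            raise SchemaError(
                f"study sample {self.sample_id!r} has unknown group "
                f"{self.group!r}")
        if not (0 < self.dilution <= 1):
            raise SchemaError(
                f"sample {self.sample_id!r}: dilution must lie in (0, 1]")
        if self.role != "qc_dilution" and self.dilution != 1.0:
            raise SchemaError(
                f"sample {self.sample_id!r}: dilution != 1 only allowed for "
                "qc_dilution samples")
        if self.dilution_stage not in DILUTION_STAGES:
            raise SchemaError(
                f"sample {self.sample_id!r}: unknown dilution_stage "
                f"{self.dilution_stage!r}")
        if self.injection_order < 1:
            raise SchemaError(
                f"sample {self.sample_id!r}: injection_order must be >= 1")


@dataclass(frozen=True)
class Metabolite:
    """One annotated metabolite: name, retention time (min), m/z."""

    name: str
    rt: float = math.nan
    mz: float = math.nan


class PeakTable:
    """Samples x metabolites peak areas with metadata and a stage tag."""

    def __init__(
        self,
        samples: Sequence[SampleMeta],
        metabolites: Sequence[Metabolite],
        areas: np.ndarray,
        stage: str = "raw",
    ) -> None:
        samples = list(samples)
        metabolites = list(metabolites)
        areas = np.asarray(areas, dtype=float)
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}")
        if areas.ndim != 2 or areas.shape != (len(samples), len(metabolites)):
            raise SchemaError(
                f"area matrix shape {areas.shape} does not match "
                f"{len(samples)} samples x {len(metabolites)} metabolites")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate sample_id: {dup}")
        names = [m.name for m in metabolites]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate metabolite names")
        if not np.all(np.isfinite(areas)):
            raise SchemaError("area matrix contains non-finite values")
        if stage in ("raw", "qc_normalized", "tss") and np.any(areas < 0):
            raise SchemaError(f"negative areas not allowed at stage {stage!r}")
        if stage == "tss":
            sums = areas.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise SchemaError("tss-stage rows must sum to 1 within 1e-9")
        self.samples = samples
        self.metabolites = metabolites
        self.areas = areas
        self.stage = stage

    # -- basic introspection ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def metabolite_names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([s.role == role for s in self.samples])

    @property
    def study_mask(self) -> np.ndarray:
        return self.role_mask("study")

    def group_mask(self, group: str) -> np.ndarray:
        return np.array(
            [s.role == "study" and s.group == group for s in self.samples])

    # -- derived tables -----------------------------------------------------

    def advance(self, areas: np.ndarray, stage: str) -> "PeakTable":
        """Return a new table at the next stage; enforces the stage order."""
        if (self.stage, stage) not in _ALLOWED_TRANSITIONS:
            raise StageError(
                f"illegal stage transition {self.stage!r} -> {stage!r}")
        return PeakTable(self.samples, self.metabolites, areas, stage)

    def subset_metabolites(self, keep: Iterable[int] | np.ndarray) -> "PeakTable":
        idx = np.asarray(list(keep), dtype=int)
        mets = [self.metabolites[i] for i in idx]
        return PeakTable(self.samples, mets, self.areas[:, idx], self.stage)

    def subset_samples(self, keep: Iterable[int] | np.ndarray) -> "PeakTable":
        idx = np.asarray(list(keep), dtype=int)
        samples = [self.samples[i] for i in idx]
        return PeakTable(samples, self.metabolites, self.areas[idx, :],
                         self.stage)

    def contrast_values(
        self, contrast: tuple[str, str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) for a two-group contrast, y=+1 for the first group.

        Sample order is preserved; only study samples of the two groups
        enter.  Raises :class:`ContrastError` when a group is missing.
        """
        a, b = contrast
        mask_a, mask_b = self.group_mask(a), self.group_mask(b)
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ContrastError(
                f"contrast {a} vs {b}: missing group "
                f"({a}: {int(mask_a.sum())}, {b}: {int(mask_b.sum())})")
        mask = mask_a | mask_b
        X = self.areas[mask]
        y = np.where(mask_a[mask], 1, -1)
        return X, y

    def to_frame(self) -> pd.DataFrame:
        """Metadata columns followed by one column per metabolite."""
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": [s.group for s in self.samples],
                "role": [s.role for s in self.samples],
                "dilution": [s.dilution for s in self.samples],
                "dilution_stage": [s.dilution_stage for s in self.samples],
                "injection_order": [s.injection_order for s in self.samples],
            }
        )
        area = pd.DataFrame(self.areas, columns=self.metabolite_names)
        return pd.concat([meta, area], axis=1)


def parse_contrast(text: str) -> tuple[str, str]:
    """Parse 'A:B' into an ordered group pair (first-listed = positive)."""
    parts = text.split(":")
    if len(parts) != 2 or not all(p in GROUPS for p in parts):
        raise ContrastError(
            f"contrast must be 'A:B' with groups from {GROUPS}; got {text!r}")
    return parts[0], parts[1]


def contrast_name(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}:{contrast[1]}"
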