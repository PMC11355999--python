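"""Run configuration: every statistical gate and tuning knob in one record.

The defaults encode the study conventions: Benjamini-Hochberg FDR at
q < 0.05 with fold-change gates > 1.25 / < 0.75 for differential-metabolite
calls, an AUC > 0.9 marker gate, 10-times-repeated 3-fold cross-validation
for the classifiers, strict 20 % immobility thresholds for phenotyping, and
|r| > 0.4 with p < 0.05 for metabolite-behavior correlations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    """All thresholds, CV settings and switches for one analysis run."""

    fdr_alpha: float = 0.05
    fc_up: float = 1.25
    fc_down: float = 0.75
    auc_gate: float = 0.9
    cv_folds: int = 3
    cv_repeats: int = 10
    rng_seed: int = 0
    qc_cv_max: float = 30.0          # percent
    qc_linearity_r2_min: float = 0.9
    immobility_increase_pct: float = 20.0
    immobility_decrease_pct: float = 20.0
    correlation_r_min: float = 0.4
    correlation_p_max: float = 0.05
    # switches (defaults follow the MetaboAnalyst-style conventions)
    equal_var_ttest: bool = True       # Student t; False -> Welch
    fc_on_tss: bool = True             # fold change on TSS areas; False -> raw
    plsda_scale: bool = False          # unit-variance scaling off by default
    plsda_cv: str = "loo"              # "loo" or "kfold"
    cutoff_criterion: str = "closest_topleft"  # or "youden"
    svm_c: float = 1.0
    svm_max_steps: int | None = None   # None -> floor(m/2)
    correlation_scale: str = "log"     # "log" or "raw"

    def __post_init__(self) -> None:
        def require(ok: bool, key: str, bound: str) -> None:
            if not ok:
                raise ConfigError(f"config key '{key}' violates bound: {bound}")

        require(0 < self.fdr_alpha < 1, "fdr_alpha", "0 < fdr_alpha < 1")
        require(self.fc_down < 1 < self.fc_up, "fc_up/fc_down",
                "fc_down < 1 < fc_up")
        require(0 < self.auc_gate < 1, "auc_gate", "0 < auc_gate < 1")
        require(self.cv_folds >= 2, "cv_folds", "cv_folds >= 2")
        require(self.cv_repeats >= 1, "cv_repeats", "cv_repeats >= 1")
        require(self.qc_cv_max > 0, "qc_cv_max", "qc_cv_max > 0")
        require(0 < self.qc_linearity_r2_min <= 1, "qc_linearity_r2_min",
                "0 < qc_linearity_r2_min <= 1")
        require(self.immobility_increase_pct > 0, "immobility_increase_pct",
                "> 0")
        require(self.immobility_decrease_pct > 0, "immobility_decrease_pct",
                "> 0")
        require(0 < self.correlation_r_min < 1, "correlation_r_min",
                "0 < correlation_r_min < 1")
        require(0 < self.correlation_p_max < 1, "correlation_p_max",
                "0 < correlation_p_max < 1")
        require(self.plsda_cv in ("loo", "kfold"), "plsda_cv",
                "one of {'loo', 'kfold'}")
        require(self.cutoff_criterion in ("closest_topleft", "youden"),
                "cutoff_criterion", "one of {'closest_topleft', 'youden'}")
        require(self.svm_c > 0, "svm_c", "svm_c > 0")
        require(self.correlation_scale in ("log", "raw"), "correlation_scale",
                "one of {'log', 'raw'}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unspecified keys take the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
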