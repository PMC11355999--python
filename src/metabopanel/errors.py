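"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MetaboPanelError` so callers can
trap pipeline failures without masking programming errors.
"""


class MetaboPanelError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MetaboPanelError):
    """A table is structurally invalid (missing column, duplicate id, ...)."""


class ParseError(MetaboPanelError):
    """A cell could not be parsed (non-numeric or negative area, ...)."""


class ConfigError(MetaboPanelError):
    """A run-configuration value is out of range or unknown."""


class StageError(MetaboPanelError):
    """A peak table was passed to a stage out of the documented order."""


class InsufficientQcError(MetaboPanelError):
    """Fewer pooled-QC injections than the drift fit requires."""


class ContrastError(MetaboPanelError):
    """A requested group contrast cannot be formed from the samples."""


class DesignError(MetaboPanelError):
    """A simulation design is infeasible or inconsistent."""


class SelectionError(MetaboPanelError):
    """Feature selection cannot run (too few features or samples)."""


class AggregationError(MetaboPanelError):
    """Cross-validated predictions do not cover every sample exactly once."""
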