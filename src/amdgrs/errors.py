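"""Exception hierarchy shared across the package."""


class AmdGrsError(Exception):
    """Base class for all package-specific errors."""


class PanelFormatError(AmdGrsError):
    """A panel config file could not be parsed or fails validation."""


class SchemaError(AmdGrsError):
    """A genotype table is missing required columns."""


class DataError(AmdGrsError):
    """A genotype table contains an invalid value (reported with location)."""


class SimulationError(AmdGrsError):
    """A cohort simulation could not satisfy its target composition."""


class CalibrationError(AmdGrsError):
    """The disease-model intercept could not be solved for the target prevalence."""


class FitError(AmdGrsError):
    """A logistic model could not be fitted (separation, rank deficiency, ...)."""


class ClassificationError(AmdGrsError):
    """Risk categories could not be formed (e.g. constant scores)."""


class ProjectionError(AmdGrsError):
    """A population projection input is out of domain."""


class ValidationError(AmdGrsError):
    """Cross-validation failed (too many unfittable splits, degenerate input)."""
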