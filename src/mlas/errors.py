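"""Exception hierarchy for the mlas package."""


class MlasError(Exception):
    """Base class for all package errors."""


class SchemaError(MlasError):
    """A required column or covariate is missing or of the wrong kind."""


class IntegrityError(MlasError):
    """Registry-level integrity violation (e.g. duplicated patient id)."""


class ValidationError(MlasError):
    """Record-level validation failure (reported with row context)."""


class ConfigurationError(MlasError):
    """A rule or model configuration references unknown inputs."""


class ConvergenceError(MlasError):
    """An iterative fit failed to converge (includes separation)."""


class DegenerateModelError(MlasError):
    """A model cannot be fit because the data carry no information
    (e.g. zero events of the target type)."""


class PositivityError(MlasError):
    """A fitted selection probability is 0 or 1, so the inverse weight
    is undefined for some patient-day."""


class EstimationError(MlasError):
    """A nonparametric estimate is undefined on the given data
    (empty risk set, degenerate ROC, ...)."""
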