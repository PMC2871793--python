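"""Exception hierarchy for the castebias pipeline.

Every stage raises a subclass of :class:`CasteBiasError`, so callers can
catch pipeline failures without masking programming errors.
"""


class CasteBiasError(Exception):
    """Base class for all castebias errors."""


class ConfigurationError(CasteBiasError, ValueError):
    """A simulation or run configuration violates one of its invariants."""


class MalformedRecordError(CasteBiasError, ValueError):
    """An input record is structurally invalid (e.g. >3 alleles at a locus)."""


class DegenerateCurveError(CasteBiasError, ValueError):
    """A standard curve cannot be fit (fewer than 2 distinct quantities)."""


class InsufficientDataError(CasteBiasError, ValueError):
    """Too few complete observations for the requested operation."""


class DomainError(CasteBiasError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class UnimputableError(CasteBiasError, ValueError):
    """A gene has no observed value in a group, so its median is undefined."""


class NormalizationError(CasteBiasError, ValueError):
    """Spectral-count normalization failed (zero spike-in or empty lane)."""


class SingularCovarianceError(CasteBiasError, ValueError):
    """Pooled covariance is singular; add ridge regularization or prune
    more features."""


class DegenerateFoldError(CasteBiasError, ValueError):
    """A cross-validation fold would leave a class empty."""


class PipelineError(CasteBiasError, RuntimeError):
    """An orchestration failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
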