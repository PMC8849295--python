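"""Exception hierarchy shared across the package.

Everything derives from :class:`PainScaleError` so callers can catch one
base class; CLI stages additionally wrap failures in :class:`StageError`
so the failing pipeline stage is always named.
"""


class PainScaleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PainScaleError):
    """A required column or field is missing from an input table."""


class TrialValidationError(PainScaleError):
    """A trial row violates a domain invariant; message carries the row index."""


class InputError(PainScaleError):
    """An operation precondition on user-supplied data is violated."""


class DegenerateFeatureError(PainScaleError):
    """A feature column is constant (zero variance) where variance is required."""


class DegenerateTrialError(PainScaleError):
    """A trajectory is degenerate for feature extraction (e.g. apex at onset)."""


class FeatureUnavailableError(PainScaleError):
    """A requested feature needs a channel that the trajectory does not carry."""


class AmbiguityError(PainScaleError):
    """A result is not uniquely defined (e.g. tied leading eigenvalues)."""


class ModelStateError(PainScaleError):
    """An operation was called on an unfitted or inconsistent model."""


class ModelVersionError(PainScaleError):
    """A serialized model has an incompatible format version."""


class ModelIntegrityError(PainScaleError):
    """A serialized model fails an internal consistency check on load."""


class PairingError(PainScaleError):
    """Paired samples do not share the same subject set."""


class StageError(PainScaleError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
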