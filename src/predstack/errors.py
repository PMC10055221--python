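"""Exception hierarchy for predstack."""


class PredstackError(Exception):
    """Base class for all predstack errors."""


class FormatError(PredstackError):
    """A file does not conform to its declared format."""


class DuplicateRecordError(FormatError):
    """The same logical record appears more than once."""


class TableValueError(PredstackError, ValueError):
    """A table cell holds an invalid value (non-finite, bad sum, ...)."""


class ConsistencyError(PredstackError):
    """Cross-record consistency violated (e.g. id in two clusters)."""


class ConfigError(PredstackError):
    """Invalid configuration object or file."""


class InputError(PredstackError):
    """An operation received arguments violating its preconditions."""


class TrainingDivergenceError(PredstackError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class CorruptModelError(PredstackError):
    """A serialized model file failed validation on load."""


class RadiusTableError(PredstackError):
    """An element has no van der Waals radius in the radius table."""


class NormalizationError(PredstackError):
    """A residue has no max-ASA normalization constant."""
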