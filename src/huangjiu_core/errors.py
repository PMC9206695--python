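"""Exception hierarchy shared by all pipeline stages."""


class HuangjiuError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(HuangjiuError):
    """Invalid configuration values or dimensions."""


class DataError(HuangjiuError):
    """Input data violate a stage's preconditions."""


class FormatError(DataError):
    """A file could not be parsed; message carries row/column coordinates."""


class AlignmentError(DataError):
    """Two inputs that must share an axis (samples, ids) do not."""


class QuantificationError(DataError):
    """A peak record cannot be converted to a concentration."""


class AnnotationError(DataError):
    """A compound is missing from the annotation table."""


class PipelineError(HuangjiuError):
    """A stage of the orchestrated pipeline failed; message names the stage."""
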