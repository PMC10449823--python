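"""Exception types shared across the package."""


class HerdidError(Exception):
    """Base class for all package errors."""


class ArgumentError(HerdidError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(HerdidError, ValueError):
    """An experiment configuration is inconsistent or malformed."""


class DataError(HerdidError, ValueError):
    """A dataset record violates the data contract (e.g. label out of range)."""


class DegenerateInputError(HerdidError, ValueError):
    """An input is structurally degenerate (e.g. an empty segmentation mask)."""


class RenderError(HerdidError, ValueError):
    """A requested pose cannot be rendered inside the camera frame."""


class UndefinedMetricError(HerdidError, ValueError):
    """A metric is undefined for the given inputs (e.g. a class absent from truth)."""
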