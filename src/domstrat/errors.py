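"""Exception hierarchy shared across the package."""


class DomstratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DomstratError):
    """Malformed input file (missing column, bad delimiter, unparseable value)."""


class ValidationError(DomstratError):
    """A record violates a data-model invariant; message names the record and rule."""


class ParameterError(DomstratError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(DomstratError):
    """Too few observations/individuals for the requested computation."""


class UnrankedIndividualError(DomstratError, KeyError):
    """An individual required by a lookup has no rank in the hierarchy."""


class PipelineError(DomstratError):
    """A pipeline stage failed; message is tagged with the stage name."""
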