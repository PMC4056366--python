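"""Exception hierarchy shared across the toolkit."""


class GcsigError(Exception):
    """Base class for all package errors."""


class ParameterError(GcsigError, ValueError):
    """An argument violates a documented precondition."""


class SizingError(ParameterError):
    """A simulation request does not fit in the requested genome."""


class PlacementError(GcsigError):
    """No eligible site exists for a requested variant class/context."""


class IntegrityError(GcsigError):
    """Input data contradicts the reference sequence or itself."""


class DataCompletenessError(GcsigError):
    """A required support/annotation row is missing for a site under test."""


class UndefinedBiasError(GcsigError):
    """Somatic/germline bias is undefined (zero germline frequency)."""
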