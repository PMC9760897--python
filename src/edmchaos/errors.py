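"""Exception hierarchy."""


class EdmChaosError(Exception):
    """Base class for all package errors."""


class FormatError(EdmChaosError):
    """Malformed input file (missing columns, bad header, ...)."""


class ValidationError(EdmChaosError):
    """Input violates a domain invariant (negative abundance, duplicate
    time stamps, species mismatch, ...)."""


class InsufficientDataError(EdmChaosError):
    """Series too short for the requested operation."""


class SingularFitError(EdmChaosError):
    """Degenerate design matrix or zero-distance weighting."""
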