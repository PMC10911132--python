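"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: validation/schema problems exit with 2,
statistical degeneracies with 3.
"""


class SbrKitError(Exception):
    """Base class for all package errors."""


class SchemaError(SbrKitError):
    """An input table or config is structurally malformed (missing column, bad enum)."""


class ValidationError(SbrKitError):
    """Structurally well-formed input violates a domain invariant (duplicate id, SBR <= 0)."""


class DegenerateDataError(SbrKitError):
    """The data cannot support the requested statistic (zero variance, single class...)."""


class CalibrationError(SbrKitError):
    """Phantom calibration is underdetermined or pathological."""
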