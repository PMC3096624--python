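"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class GmycDelimError(Exception):
    """Base class for all package errors."""


class ValidationError(GmycDelimError):
    """Invalid input data or configuration."""


class UltrametricityError(ValidationError):
    """Tree tips are not contemporaneous beyond the accepted tolerance."""


class NumericalError(GmycDelimError):
    """Optimization or likelihood evaluation failed."""
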