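"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataError/InputError -> 3, partial pipeline failure -> 4.
"""


class CdmPrivacyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CdmPrivacyError):
    """Bad profile name, malformed config document, invalid parameter."""


class ValidationError(CdmPrivacyError):
    """An object violates one of its structural invariants."""


class InputError(CdmPrivacyError):
    """A required table or column is missing from the input CDM."""


class DataError(CdmPrivacyError):
    """A cell value cannot be processed (e.g. unparseable date); carries
    row/column context in the message."""
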