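"""Package-wide exception types."""


class StnmerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StnmerError, ValueError):
    """A configuration object violates one of its invariants."""


class SessionFormatError(StnmerError, ValueError):
    """A stored session directory is malformed.

    ``code`` distinguishes the failure modes: ``missing_record``,
    ``length_mismatch``, ``schema``.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code
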