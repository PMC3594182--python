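"""Exception hierarchy shared across the package."""


class NtprocError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NtprocError, ValueError):
    """A label, file line or token could not be parsed."""


class ValidationError(NtprocError, ValueError):
    """Parsed content violates a domain invariant (e.g. illegal residue)."""


class SchemaError(NtprocError, ValueError):
    """A tabular input is missing a mandatory column."""


class InputError(NtprocError, ValueError):
    """An operation was called with arguments outside its contract."""


class UndefinedValueError(NtprocError, ValueError):
    """The requested quantity is undefined for this input
    (e.g. pI of a peptide whose charge never crosses zero,
    information content of a fully padded logo column)."""
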