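"""Exception hierarchy.

``InputError`` subclasses map to CLI exit code 2, ``NumericalError``
subclasses to exit code 3.
"""


class IcpcaError(Exception):
    """Base class for all package errors."""


class InputError(IcpcaError):
    """Malformed or inconsistent user input."""


class FormatError(InputError):
    """A structure/ensemble/charge file violates its format contract."""


class SchemaError(InputError):
    """A tabular input lacks a mandatory column."""


class AlignmentError(InputError):
    """Per-atom data does not align with the structure it annotates."""


class NumericalError(IcpcaError):
    """A computation cannot proceed (degenerate input, no variance, ...)."""
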