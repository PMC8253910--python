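"""Exception hierarchy.

``UserInputError`` marks problems a caller can fix (bad file, bad
parameter); the CLI maps it to exit code 1.  Anything else escaping a
command is an internal error (exit code 2).
"""


class MiprotError(Exception):
    """Base class for package errors."""


class UserInputError(MiprotError):
    """Invalid input data or parameters supplied by the caller."""
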