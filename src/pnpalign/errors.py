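"""Exception hierarchy.

``InputError`` covers everything the user can cause (bad files, bad
parameters); ``InvariantError`` signals an internal contract violation and
always indicates a bug.  The CLI maps them to exit codes 2 and 3.
"""


class PnpalignError(Exception):
    """Base class for all package errors."""


class InputError(PnpalignError):
    """Malformed or inconsistent user input."""


class InvariantError(PnpalignError):
    """An internal invariant was violated (pipeline bug)."""
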