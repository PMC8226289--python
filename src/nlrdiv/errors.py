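"""Exception hierarchy shared across the toolkit.

Two failure classes are distinguished so the command-line layer can map
them to distinct exit codes: malformed or inconsistent *input* versus a
violated internal *invariant* (a bug or an impossible request).
"""


class NlrdivError(Exception):
    """Base class for all toolkit errors."""


class InputError(NlrdivError):
    """Raised when user-supplied data is malformed or inconsistent."""


class InvariantError(NlrdivError):
    """Raised when an internal contract (partition disjointness, matrix
    shape, ...) is violated."""
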