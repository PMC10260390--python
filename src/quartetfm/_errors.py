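"""Exception hierarchy.

``InputError`` covers everything a user can fix (bad files, bad labels,
bad parameter values); ``StateError`` covers violated internal
preconditions; ``PassCapError`` is the MFM diagnostic escape hatch and
carries the best partition found so far.
"""


class QuartetFMError(Exception):
    """Base class for all package errors."""


class InputError(QuartetFMError):
    """Invalid user input (files, labels, weights, parameters)."""


class ParseError(InputError):
    """Malformed quartet or newick text; carries location when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InvalidQuartetError(InputError):
    """A quartet whose four taxa are not distinct (or otherwise illegal)."""


class StateError(QuartetFMError):
    """An operation was called on a partition/tree in an illegal state."""


class TreeError(QuartetFMError):
    """Structural tree errors (missing leaves, overlapping leaf sets...)."""


class PassCapError(QuartetFMError):
    """MFM exceeded its configured outer-pass cap.

    The best state reached so far is attached as ``state`` so callers can
    degrade gracefully.
    """

    def __init__(self, message, state):
        super().__init__(message)
        self.state = state
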