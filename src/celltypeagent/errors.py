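"""Exception hierarchy for the annotation pipeline.

All package errors derive from :class:`CellTypeAgentError` so callers can
catch the whole family; subclasses distinguish configuration mistakes,
empty inputs, snapshot problems, LLM-response failures, and evaluation
alignment problems.
"""

from __future__ import annotations


class CellTypeAgentError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CellTypeAgentError):
    """A parameter, column mapping, or config file is invalid."""


class EmptyInputError(CellTypeAgentError):
    """An input table or collection that must be non-empty was empty."""


class SnapshotLoadError(CellTypeAgentError):
    """A reference snapshot violated an invariant (bad value, duplicate key)."""


class SnapshotFormatError(SnapshotLoadError):
    """A reference snapshot file is not in a recognized format."""


class ResponseParseError(CellTypeAgentError):
    """No candidate cell-type names could be extracted from an LLM response."""


class InferenceError(CellTypeAgentError):
    """All LLM attempts for a cluster failed; carries the last raw response."""

    def __init__(self, message: str, raw_response: str = "", attempts: int = 0):
        super().__init__(message)
        self.raw_response = raw_response
        self.attempts = attempts


class AlignmentError(CellTypeAgentError):
    """Predicted and truth cluster sets do not match; carries the difference."""

    def __init__(self, message: str, missing: tuple[str, ...] = (), extra: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = missing
        self.extra = extra
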