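"""Exception hierarchy shared by all daswriteback modules.

Every error raised by the package derives from :class:`DasWritebackError`,
so callers (and the CLI) can catch domain errors with a single clause.
"""

from __future__ import annotations


class DasWritebackError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(DasWritebackError):
    """The input is not well-formed XML (or is otherwise unreadable)."""


class SchemaError(DasWritebackError):
    """Well-formed XML that is missing a mandatory DAS GFF element or
    attribute. The message names the offending element path."""


class ValidationError(DasWritebackError):
    """A feature violates a domain invariant.

    Carries the list of :class:`~daswriteback.validation.ValidationIssue`
    objects when raised by the validation layer.
    """

    def __init__(self, message: str, issues: list | None = None):
        super().__init__(message)
        self.issues = issues or []


class NotFoundError(DasWritebackError):
    """The addressed segment, feature or version does not exist."""


class ConflictError(DasWritebackError):
    """The operation conflicts with the current state of the feature
    (e.g. creating a live feature, updating a deleted one)."""


class InvalidTargetError(DasWritebackError):
    """A rollback target is unusable (the target version is a deletion)."""


class InputError(DasWritebackError):
    """Inconsistent or unusable arguments (segment mismatch, unknown mode,
    impossible fixture parameters)."""


class AuthenticationError(DasWritebackError):
    """Missing or invalid credentials on a write request."""
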