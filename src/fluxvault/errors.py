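"""Exception hierarchy.

Every error the library raises derives from :class:`FluxVaultError` so callers
(and the HTTP layer) can distinguish domain failures from programming bugs.
"""


class FluxVaultError(Exception):
    """Base class for all fluxvault errors."""


class ConflictError(FluxVaultError):
    """An identifier is already taken (duplicate model id, file name...)."""


class FormatError(FluxVaultError):
    """A document failed to parse or lacks mandatory content."""


class ConfigError(FluxVaultError):
    """A requested resource class is not configured (e.g. translation pair)."""


class NotFoundError(FluxVaultError):
    """A named object does not exist in the store."""


class StructureError(FluxVaultError):
    """A document is self-inconsistent (e.g. an edge with a dangling endpoint)."""


class ConsistencyError(FluxVaultError):
    """A document is internally valid but disagrees with the referenced model."""


class LineageError(FluxVaultError):
    """The parent chain of a modification file is cyclic."""


class MissingReferenceError(FluxVaultError):
    """A modification file references a parent absent from the store."""


class StateError(FluxVaultError):
    """An operation was applied to a solution/object in the wrong state."""


class SolverError(FluxVaultError):
    """The LP solver failed for a reason other than infeasible/unbounded."""

    def __init__(self, message: str, status: str = "error"):
        super().__init__(message)
        self.status = status
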