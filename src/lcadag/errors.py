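"""Exception hierarchy shared across the package."""


class LcadagError(Exception):
    """Base class for all package-specific errors."""


class GraphValidationError(LcadagError, ValueError):
    """A graph or cluster system failed structural validation."""


class NotADAGError(GraphValidationError):
    """The supplied edge set contains a directed cycle."""


class InvalidEdgeError(GraphValidationError):
    """An edge is malformed (self-loop or otherwise inadmissible)."""


class UnknownVertexError(GraphValidationError):
    """A vertex label does not occur in the graph."""


class InvalidQueryError(LcadagError, ValueError):
    """An LCA query set is empty or contains non-leaf labels."""


class WorkBoundExceededError(LcadagError, RuntimeError):
    """An exhaustive subset search would exceed the configured work bound.

    Deciding whether a vertex is a k-LCA or k-lca vertex for a *given* k is
    NP-complete on general DAGs, so explicit-k queries outside the N3O class
    fall back to subset enumeration guarded by a work bound.  Exceeding the
    bound raises this error rather than silently approximating.
    """


class FileFormatError(LcadagError, ValueError):
    """A DAG or cluster file is malformed."""
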