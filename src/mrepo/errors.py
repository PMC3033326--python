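"""Exception hierarchy.

Every error the engine raises derives from :class:`MrepoError`, so callers
(and the CLI) can map failure classes to exit codes without string matching.
"""


class MrepoError(Exception):
    """Base class for all repository-engine errors."""


class ValidationError(MrepoError):
    """Input violates a structural precondition (bad path, >2 parents, ...)."""


class NotFoundError(MrepoError):
    """A revision, object, mount or exposure id does not resolve."""


class IntegrityError(MrepoError):
    """A store or bundle is internally inconsistent (missing parent/object,
    digest mismatch, cycle in what must be a DAG)."""


class PermissionDeniedError(MrepoError):
    """The acting principal is not authorized for the requested action."""


class NoCommonAncestorError(MrepoError):
    """Two revisions share no history; a merge base does not exist."""


class FastForwardError(MrepoError):
    """Merge target is a descendant of the working revision: there is
    nothing to reconcile, update to the head instead of fabricating a
    two-parent changeset."""


class MountConflictError(MrepoError):
    """An embedding mount point collides with a file or another mount."""


class DanglingMountError(MrepoError):
    """An embedded workspace or its pinned revision cannot be resolved."""


class UnresolvedImportError(MrepoError):
    """A model file imports an href that does not resolve inside the tree."""


class ImportCycleError(MrepoError):
    """The import graph of a model contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("import cycle: " + " -> ".join(self.cycle))


class PathEscapeError(MrepoError):
    """A relative href climbs above the workspace root."""


class RankDeficiencyError(MrepoError):
    """The regression design matrix is rank-deficient (single factor level
    or collinear covariate)."""
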