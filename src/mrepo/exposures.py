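"""Exposures, role-based authorization, and linear-series migration.

Not every revision pushed to a workspace should be advertised: a commit
may fix one issue while leaving the model temporarily less usable, or may
not yet have been peer reviewed.  An *exposure* is therefore a curated
pointer to one specific revision of a workspace, carrying documentation, an
optional publication reference (PubMed id) and per-tool curation results.
Model authors commit and push freely to their own workspaces; only the
final act of creating an exposure is restricted to curators.

Exposures live in a catalog outside version control (a JSON document), so
creating one never touches workspace history, and the binding
(workspace, revision) is immutable once created.

``migrate_linear`` converts the legacy storage scheme -- a linear series of
ordinal versions -- into a chain of changesets, preserving each version's
date of addition as the commit date.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .core import Workspace
from .errors import NotFoundError, PermissionDeniedError, ValidationError

__all__ = [
    "Principal",
    "RoleRegistry",
    "AuthzDecision",
    "authorize",
    "Exposure",
    "ExposureCatalog",
    "Version",
    "VersionSeries",
    "migrate_linear",
]


# -- principals and authorization -------------------------------------------

_ACTIONS = frozenset({"push", "create_exposure"})
_ROLES = frozenset({"author", "curator"})


@dataclass(frozen=True)
class Principal:
    """A registered user: roles plus the workspaces they own."""

    name: str
    roles: frozenset[str] = frozenset()
    owned_workspaces: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "roles", frozenset(self.roles))
        object.__setattr__(self, "owned_workspaces", frozenset(self.owned_workspaces))
        if not self.roles:
            raise ValidationError(f"principal {self.name!r} has no roles")
        unknown = self.roles - _ROLES
        if unknown:
            raise ValidationError(f"unknown roles {sorted(unknown)} for {self.name!r}")


class AuthzDecision:
    """Boolean decision carrying the reason; truthy iff allowed."""

    def __init__(self, allowed: bool, reason: str):
        self.allowed = allowed
        self.reason = reason

    def __bool__(self) -> bool:
        return self.allowed

    def __repr__(self) -> str:
        verdict = "allow" if self.allowed else "deny"
        return f"AuthzDecision({verdict}: {self.reason})"


def authorize(principal: Principal | None, action: str, ws_uri: str) -> AuthzDecision:
    """Total, default-deny policy.

    ``push``: allowed to the owner of the workspace and to curators (who
    may need to push anywhere they curate).  ``create_exposure``: curators
    only, regardless of ownership.
    """
    if action not in _ACTIONS:
        return AuthzDecision(False, f"unknown action {action!r}")
    if principal is None:
        return AuthzDecision(False, "unknown principal")
    if action == "push":
        if ws_uri in principal.owned_workspaces:
            return AuthzDecision(True, f"{principal.name} owns {ws_uri}")
        if "curator" in principal.roles:
            return AuthzDecision(True, f"{principal.name} is a curator")
        return AuthzDecision(False, f"{principal.name} does not own {ws_uri} and is not a curator")
    if "curator" in principal.roles:
        return AuthzDecision(True, f"{principal.name} is a curator")
    return AuthzDecision(False, "creating an exposure is restricted to curators")


class RoleRegistry:
    """Principals parsed from a plain-text roles file.

    Lines are ``principal:role`` (role in {author, curator}) or
    ``principal:owns:<workspace-uri>``; blank lines and ``#`` comments are
    ignored.  Unknown principals resolve to None (default deny).
    """

    def __init__(self, principals: Mapping[str, Principal] | None = None):
        self._principals = dict(principals or {})

    @classmethod
    def parse(cls, text: str) -> "RoleRegistry":
        roles: dict[str, set[str]] = {}
        owns: dict[str, set[str]] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(":", 2)
            if len(parts) == 2:
                roles.setdefault(parts[0], set()).add(parts[1])
            elif len(parts) == 3 and parts[1] == "owns":
                owns.setdefault(parts[0], set()).add(parts[2])
            else:
                raise ValidationError(f"malformed roles line {lineno}: {raw!r}")
        principals = {
            name: Principal(name, frozenset(r), frozenset(owns.get(name, set())))
            for name, r in roles.items()
        }
        for name in owns:
            if name not in principals:
                raise ValidationError(f"{name!r} owns workspaces but has no role line")
        return cls(principals)

    @classmethod
    def load(cls, path: str | Path) -> "RoleRegistry":
        return cls.parse(Path(path).read_text(encoding="utf-8"))

    def get(self, name: str) -> Principal | None:
        return self._principals.get(name)


# -- exposures ---------------------------------------------------------------

@dataclass(frozen=True)
class Exposure:
    """Curated pointer to one revision of one workspace."""

    id: str
    workspace_uri: str
    revision: str
    title: str
    documentation: str = ""
    pubmed_id: str | None = None
    curation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "curation", dict(self.curation))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "workspace_uri": self.workspace_uri,
            "revision": self.revision,
            "title": self.title,
            "documentation": self.documentation,
            "pubmed_id": self.pubmed_id,
            "curation": dict(self.curation),
        }


class ExposureCatalog:
    """The repository-wide exposure collection, persisted as one JSON
    document; exposures are append-only and never rebound."""

    def __init__(self):
        self._exposures: dict[str, Exposure] = {}

    def __len__(self) -> int:
        return len(self._exposures)

    def __iter__(self):
        return iter(self._exposures.values())

    def get(self, exposure_id: str) -> Exposure:
        try:
            return self._exposures[exposure_id]
        except KeyError:
            raise NotFoundError(f"unknown exposure {exposure_id!r}") from None

    def create_exposure(
        self,
        principal: Principal | None,
        ws: Workspace,
        rev: str,
        *,
        exposure_id: str | None = None,
        title: str,
        documentation: str = "",
        pubmed_id: str | None = None,
        curation: Mapping[str, str] | None = None,
    ) -> Exposure:
        """Create an exposure of ``rev`` in ``ws``; curators only.

        The revision need not be the workspace head: the latest revision is
        not always the one that should be advertised.
        """
        decision = authorize(principal, "create_exposure", ws.uri)
        if not decision:
            raise PermissionDeniedError(decision.reason)
        cs = ws.changeset(rev)  # NotFoundError if absent
        if exposure_id is None:
            exposure_id = f"exposure-{len(self._exposures) + 1:04d}"
        if exposure_id in self._exposures:
            raise ValidationError(f"exposure id {exposure_id!r} already in use")
        exposure = Exposure(
            id=exposure_id,
            workspace_uri=ws.uri,
            revision=cs.id,
            title=title,
            documentation=documentation,
            pubmed_id=pubmed_id,
            curation=curation or {},
        )
        self._exposures[exposure_id] = exposure
        return exposure

    def exposures_for(self, ws_uri: str) -> dict[str, list[Exposure]]:
        """All exposures of a workspace, keyed by revision id.  A revision
        may carry several exposures, so values are lists."""
        result: dict[str, list[Exposure]] = {}
        for exposure in self._exposures.values():
            if exposure.workspace_uri == ws_uri:
                result.setdefault(exposure.revision, []).append(exposure)
        return result

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {"exposures": [e.to_dict() for e in self._exposures.values()]}
        Path(path).write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ExposureCatalog":
        catalog = cls()
        if not Path(path).exists():
            return catalog
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        for item in doc.get("exposures", []):
            exposure = Exposure(
                id=item["id"],
                workspace_uri=item["workspace_uri"],
                revision=item["revision"],
                title=item["title"],
                documentation=item.get("documentation", ""),
                pubmed_id=item.get("pubmed_id"),
                curation=item.get("curation", {}),
            )
            catalog._exposures[exposure.id] = exposure
        return catalog


# -- migration of linear version series --------------------------------------

@dataclass(frozen=True)
class Version:
    """One ordinal version from the legacy scheme."""

    tree: Mapping[str, bytes]
    timestamp: int
    tz_offset: int = 0
    label: str = ""


@dataclass
class VersionSeries:
    """The legacy storage scheme: ordered versions, dates non-decreasing."""

    versions: list[Version]

    def __post_init__(self):
        if not self.versions:
            raise ValidationError("a version series must contain at least one version")
        for earlier, later in zip(self.versions, self.versions[1:]):
            if later.timestamp < earlier.timestamp:
                raise ValidationError("version dates must be non-decreasing")


def migrate_linear(series: VersionSeries, ws_uri: str, author: str) -> Workspace:
    """Replay a linear version series as a chain of changesets.

    Each version becomes one changeset whose commit date is the version's
    date of addition and whose message is the version label; checkout of
    the k-th changeset reproduces the k-th input tree byte-identically.
    """
    ws = Workspace(ws_uri)
    parent: list[str] = []
    for version in series.versions:
        cs = ws.commit(
            dict(version.tree),
            author=author,
            timestamp=version.timestamp,
            tz_offset=version.tz_offset,
            message=version.label,
            parents=parent,
        )
        parent = [cs.id]
    return ws
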