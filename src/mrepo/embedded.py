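"""Embedded workspaces and relative-URI import resolution.

A multi-file model often imports a generic sub-model -- say an ion-channel
model -- maintained in its own workspace.  Embedding mounts that child
workspace inside the parent's tree at a *pinned* revision, so the parent
controls exactly which version of the sub-model it imports and can address
it with relative URIs.  The pin lives in two tracked files at the parent
root, so it is versioned like any other change and historical checkouts
reproduce historical pins:

* ``EMBEDDED``       -- one ``<mount-path> = <workspace-uri>`` line per mount;
* ``EMBEDDED.state`` -- one ``<revision-id> <mount-path>`` line per mount;

both UTF-8, LF line endings, entries sorted by mount path.

Import resolution walks a reduced CellML-1.1-style import graph: any XML
element whose local name is ``import`` and which carries an ``href``
attribute (any namespace) names a dependency, resolved relative to the
importing file's directory.  Only relative hrefs are followed; absolute
URIs are recorded as edges but never fetched.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass, field
from typing import Callable, Mapping

from lxml import etree

from .core import Workspace, validate_path
from .errors import (
    DanglingMountError,
    ImportCycleError,
    MountConflictError,
    NotFoundError,
    PathEscapeError,
    UnresolvedImportError,
    ValidationError,
)

__all__ = [
    "EMBEDDED_FILE",
    "STATE_FILE",
    "EmbeddingSpec",
    "WorkspaceRegistry",
    "embed",
    "update_embedded",
    "checkout_recursive",
    "ImportClosure",
    "resolve_imports",
]

EMBEDDED_FILE = "EMBEDDED"
STATE_FILE = "EMBEDDED.state"

MAX_NESTING_DEPTH = 8  # bounds recursion on malformed (self-embedding) fixtures


class WorkspaceRegistry:
    """Resolves workspace URIs to workspaces.

    In-memory mapping by default; a loader callable can back it (the CLI
    uses one that opens sibling directories).
    """

    def __init__(self, loader: Callable[[str], Workspace] | None = None):
        self._workspaces: dict[str, Workspace] = {}
        self._loader = loader

    def add(self, ws: Workspace) -> None:
        self._workspaces[ws.uri] = ws

    def remove(self, uri: str) -> None:
        self._workspaces.pop(uri, None)

    def resolve(self, uri: str) -> Workspace:
        if uri in self._workspaces:
            return self._workspaces[uri]
        if self._loader is not None:
            try:
                ws = self._loader(uri)
            except Exception as exc:
                raise DanglingMountError(f"cannot resolve workspace {uri!r}: {exc}") from exc
            self._workspaces[uri] = ws
            return ws
        raise DanglingMountError(f"cannot resolve workspace {uri!r}")


@dataclass
class EmbeddingSpec:
    """Pinned mounts of a workspace: mount path -> (child URI, revision)."""

    mounts: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tree(cls, tree: Mapping[str, bytes]) -> "EmbeddingSpec":
        uris: dict[str, str] = {}
        pins: dict[str, str] = {}
        if EMBEDDED_FILE in tree:
            for line in tree[EMBEDDED_FILE].decode("utf-8").splitlines():
                if not line.strip():
                    continue
                mount, sep, uri = line.partition(" = ")
                if not sep:
                    raise ValidationError(f"malformed {EMBEDDED_FILE} line: {line!r}")
                uris[mount] = uri
        if STATE_FILE in tree:
            for line in tree[STATE_FILE].decode("utf-8").splitlines():
                if not line.strip():
                    continue
                rev, sep, mount = line.partition(" ")
                if not sep:
                    raise ValidationError(f"malformed {STATE_FILE} line: {line!r}")
                pins[mount] = rev
        if set(uris) != set(pins):
            raise ValidationError(
                f"{EMBEDDED_FILE} and {STATE_FILE} disagree on mounts: "
                f"{sorted(set(uris) ^ set(pins))}"
            )
        return cls({mount: (uris[mount], pins[mount]) for mount in uris})

    def to_files(self) -> dict[str, bytes]:
        order = sorted(self.mounts)
        embedded = "".join(f"{m} = {self.mounts[m][0]}\n" for m in order)
        state = "".join(f"{self.mounts[m][1]} {m}\n" for m in order)
        return {
            EMBEDDED_FILE: embedded.encode("utf-8"),
            STATE_FILE: state.encode("utf-8"),
        }


def _check_mount(spec: EmbeddingSpec, tree: Mapping[str, bytes], mount: str) -> None:
    validate_path(mount)
    for existing in spec.mounts:
        if existing == mount or existing.startswith(mount + "/") or mount.startswith(existing + "/"):
            raise MountConflictError(f"mount {mount!r} overlaps existing mount {existing!r}")
    for path in tree:
        if path == mount or path.startswith(mount + "/"):
            raise MountConflictError(f"mount {mount!r} collides with tracked file {path!r}")


def embed(
    ws: Workspace, mount: str, child_uri: str, child_rev: str, registry: WorkspaceRegistry
) -> EmbeddingSpec:
    """Mount ``child_uri`` at ``mount`` pinned to ``child_rev``, updating
    the tracked pin files in the working tree (to be committed like any
    other change)."""
    child = registry.resolve(child_uri)
    if child_rev not in child:
        raise NotFoundError(f"revision {child_rev[:12]} not in workspace {child_uri!r}")
    spec = EmbeddingSpec.from_tree(ws.worktree)
    _check_mount(spec, ws.worktree, mount)
    spec.mounts[mount] = (child_uri, child_rev)
    ws.worktree.update(spec.to_files())
    return spec


def update_embedded(
    ws: Workspace, mount: str, new_rev: str, registry: WorkspaceRegistry
) -> EmbeddingSpec:
    """Re-pin an existing mount to ``new_rev``; only the state entry for
    that mount changes -- the importing model files are untouched."""
    spec = EmbeddingSpec.from_tree(ws.worktree)
    if mount not in spec.mounts:
        raise NotFoundError(f"no embedded workspace mounted at {mount!r}")
    uri, current = spec.mounts[mount]
    child = registry.resolve(uri)
    if new_rev not in child:
        raise NotFoundError(f"revision {new_rev[:12]} not in workspace {uri!r}")
    if new_rev == current:
        return spec
    spec.mounts[mount] = (uri, new_rev)
    ws.worktree.update(spec.to_files())
    return spec


def checkout_recursive(
    ws: Workspace,
    rev: str,
    registry: WorkspaceRegistry,
    max_depth: int = MAX_NESTING_DEPTH,
) -> dict[str, bytes]:
    """Tree at ``rev`` with every mount replaced by the child tree at its
    pinned revision, recursively.

    The pin files read are those AT ``rev``, so checking out an older
    parent revision reproduces the older pins, and later commits in the
    child never leak into an already-pinned checkout.
    """
    if max_depth < 0:
        raise ValidationError("embedded workspace nesting exceeds the depth limit")
    tree = ws.checkout(rev)
    spec = EmbeddingSpec.from_tree(tree)
    for mount, (uri, pin) in spec.mounts.items():
        try:
            child = registry.resolve(uri)
        except DanglingMountError as exc:
            raise DanglingMountError(f"mount {mount!r}: {exc}") from exc
        if pin not in child:
            raise DanglingMountError(
                f"mount {mount!r}: pinned revision {pin[:12]} missing from {uri!r}"
            )
        subtree = checkout_recursive(child, pin, registry, max_depth - 1)
        for sub_path, content in subtree.items():
            tree[f"{mount}/{sub_path}"] = content
    return tree


# -- import resolution -------------------------------------------------------

@dataclass
class ImportClosure:
    """Files reachable from a top-level model file through import edges.

    ``files`` lists (path, bytes) in breadth-first order starting at the
    top-level file; ``edges`` lists (importer-path, href, resolved-path),
    with ``resolved-path`` None for absolute URIs (recorded, not fetched).
    """

    files: list[tuple[str, bytes]]
    edges: list[tuple[str, str, str | None]]


def _is_absolute_uri(href: str) -> bool:
    scheme, sep, _ = href.partition(":")
    return bool(sep) and scheme.replace("+", "").replace("-", "").replace(".", "").isalnum()


def _import_hrefs(data: bytes, path: str) -> list[str]:
    try:
        doc = etree.fromstring(data)
    except etree.XMLSyntaxError:
        return []  # non-XML companion file: a leaf of the closure
    hrefs = []
    for element in doc.iter():
        if not isinstance(element.tag, str) or etree.QName(element).localname != "import":
            continue
        for name, value in element.attrib.items():
            if etree.QName(name).localname == "href":
                hrefs.append(value)
    return hrefs


def _resolve_href(importer: str, href: str) -> str:
    joined = posixpath.join(posixpath.dirname(importer), href)
    normalized = posixpath.normpath(joined)
    if normalized.startswith("..") or normalized.startswith("/"):
        raise PathEscapeError(f"href {href!r} in {importer!r} escapes the tree root")
    return normalized


def resolve_imports(tree: Mapping[str, bytes], top: str) -> ImportClosure:
    """Breadth-first import closure of ``top`` within ``tree``.

    Hrefs resolve relative to the importing file's directory with ``.`` and
    ``..`` segments normalised.  Errors: a relative href that names no file
    in the tree, an import cycle (the cycle is reported), or an href that
    climbs above the tree root.
    """
    if top not in tree:
        raise NotFoundError(f"top-level file {top!r} not in tree")
    try:
        etree.fromstring(tree[top])
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"top-level file {top!r} is not well-formed XML: {exc}") from exc

    edges: list[tuple[str, str, str | None]] = []
    adjacency: dict[str, list[str]] = {}

    def visit(path: str, stack: tuple[str, ...]) -> None:
        if path in stack:
            raise ImportCycleError(stack[stack.index(path):] + (path,))
        if path in adjacency:
            return
        adjacency[path] = []
        for href in _import_hrefs(tree[path], path):
            if _is_absolute_uri(href):
                edges.append((path, href, None))
                continue
            resolved = _resolve_href(path, href)
            if resolved not in tree:
                raise UnresolvedImportError(
                    f"{path!r} imports {href!r}, which does not resolve in the tree"
                )
            edges.append((path, href, resolved))
            adjacency[path].append(resolved)
            visit(resolved, stack + (path,))

    visit(top, ())

    ordered: list[str] = []
    seen = {top}
    queue = [top]
    while queue:
        current = queue.pop(0)
        ordered.append(current)
        for nxt in adjacency[current]:
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return ImportClosure([(p, tree[p]) for p in ordered], edges)
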