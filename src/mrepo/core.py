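"""Content-addressed object store and changeset DAG.

A *workspace* is one version-controlled repository holding the files of a
model (or a few closely related models).  Its history is a directed acyclic
graph of *changesets*: each changeset snapshots the complete file tree via a
manifest, and carries author, date and message plus links to 0, 1 or 2
parent changesets.  Two parents denote a merge; allowing them is what lets
independently developed variants of a model be reconciled without losing
which changes have already flowed where.

Everything versioned -- file blobs, manifests, changeset records -- lives in
one content-addressed object store keyed by the SHA-256 digest of the
object's bytes.  Changeset identifiers are therefore pure functions of
content and history: replaying the same commits in a fresh workspace
reproduces every id, which is what makes exchanging changes between
repositories well-defined.

Canonical serializations (these define the identifiers, so they are frozen):

* manifest: one ``<path>\\t<object-id>\\n`` line per file, paths in strict
  lexicographic byte order;
* changeset: ``manifest <id>``, one ``parent <id>`` line per parent in
  order (first parent is the local side of a merge), ``author <name>``,
  ``date <epoch-seconds> <tz-offset-minutes>``, a blank line, then the
  message; LF line endings throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, NotFoundError, ValidationError

__all__ = [
    "hash_content",
    "validate_path",
    "Manifest",
    "Changeset",
    "Workspace",
    "parse_iso8601",
    "format_iso8601",
]

_HEX_DIGITS = set("0123456789abcdef")


def hash_content(content: bytes) -> str:
    """SHA-256 digest of ``content`` as 64 lowercase hex characters."""
    return hashlib.sha256(content).hexdigest()


def _check_object_id(hex_id: str) -> str:
    if not (isinstance(hex_id, str) and len(hex_id) == 64 and set(hex_id) <= _HEX_DIGITS):
        raise ValidationError(f"malformed object id: {hex_id!r}")
    return hex_id


def validate_path(path: str) -> str:
    """Check that ``path`` is a well-formed manifest path.

    Paths are POSIX-style, relative, with no empty, ``.`` or ``..``
    segments and no backslashes; this keeps a manifest unambiguous across
    platforms and rules out escapes from the tree root.
    """
    if not isinstance(path, str) or not path:
        raise ValidationError("manifest path must be a non-empty string")
    if path.startswith("/") or "\\" in path:
        raise ValidationError(f"manifest path must be relative POSIX-style: {path!r}")
    for segment in path.split("/"):
        if segment in ("", ".", ".."):
            raise ValidationError(f"illegal path segment in {path!r}")
    return path


# -- timestamps --------------------------------------------------------------

def parse_iso8601(text: str) -> tuple[int, int]:
    """Parse an ISO-8601 instant into (epoch seconds, tz offset minutes).

    A bare local time (no offset) is taken as UTC.
    """
    raw = text.strip()
    try:
        dt = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    except ValueError as exc:
        raise ValidationError(f"unparseable timestamp: {text!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    offset = int(dt.utcoffset().total_seconds() // 60)
    return int(dt.timestamp()), offset


def format_iso8601(timestamp: int, tz_offset: int) -> str:
    tz = timezone(timedelta(minutes=tz_offset))
    return datetime.fromtimestamp(timestamp, tz).isoformat()


# -- manifests ---------------------------------------------------------------

@dataclass(frozen=True)
class Manifest:
    """Snapshot of a workspace tree: mapping of path -> blob object id."""

    entries: Mapping[str, str]

    def __post_init__(self):
        validated = {}
        for path, oid in dict(self.entries).items():
            validated[validate_path(path)] = _check_object_id(oid)
        object.__setattr__(self, "entries", validated)

    def serialize(self) -> bytes:
        lines = [
            f"{path}\t{self.entries[path]}\n"
            for path in sorted(self.entries, key=lambda p: p.encode("utf-8"))
        ]
        return "".join(lines).encode("utf-8")

    @classmethod
    def parse(cls, data: bytes) -> "Manifest":
        entries: dict[str, str] = {}
        for line in data.decode("utf-8").splitlines():
            path, sep, oid = line.partition("\t")
            if not sep:
                raise IntegrityError(f"malformed manifest line: {line!r}")
            if path in entries:
                raise IntegrityError(f"duplicate manifest path: {path!r}")
            entries[path] = oid
        return cls(entries)


# -- changesets --------------------------------------------------------------

@dataclass(frozen=True)
class Changeset:
    """One node of the revision DAG.

    ``id`` is the SHA-256 digest of :meth:`serialize`, so the identifier
    commits to the snapshot, the metadata and the full ancestry.
    """

    id: str
    parents: tuple[str, ...]
    manifest: str
    author: str
    timestamp: int
    tz_offset: int
    message: str

    @staticmethod
    def serialize_fields(
        manifest: str,
        parents: Iterable[str],
        author: str,
        timestamp: int,
        tz_offset: int,
        message: str,
    ) -> bytes:
        lines = [f"manifest {manifest}"]
        lines += [f"parent {p}" for p in parents]
        lines.append(f"author {author}")
        lines.append(f"date {int(timestamp)} {int(tz_offset)}")
        head = "\n".join(lines)
        return (head + "\n\n" + message).encode("utf-8")

    @classmethod
    def create(
        cls,
        manifest: str,
        parents: Iterable[str],
        author: str,
        timestamp: int,
        tz_offset: int,
        message: str,
    ) -> "Changeset":
        parents = tuple(parents)
        data = cls.serialize_fields(manifest, parents, author, timestamp, tz_offset, message)
        return cls(
            id=hash_content(data),
            parents=parents,
            manifest=manifest,
            author=author,
            timestamp=int(timestamp),
            tz_offset=int(tz_offset),
            message=message,
        )

    def serialize(self) -> bytes:
        return self.serialize_fields(
            self.manifest, self.parents, self.author, self.timestamp, self.tz_offset, self.message
        )

    @classmethod
    def parse(cls, data: bytes) -> "Changeset":
        text = data.decode("utf-8")
        head, sep, message = text.partition("\n\n")
        if not sep:
            raise IntegrityError("malformed changeset record: no blank line")
        manifest = None
        parents: list[str] = []
        author = None
        date = None
        for line in head.split("\n"):
            key, _, value = line.partition(" ")
            if key == "manifest":
                manifest = value
            elif key == "parent":
                parents.append(value)
            elif key == "author":
                author = value
            elif key == "date":
                date = value
            else:
                raise IntegrityError(f"unknown changeset field: {key!r}")
        if manifest is None or author is None or date is None:
            raise IntegrityError("changeset record missing required field")
        ts_str, _, off_str = date.partition(" ")
        return cls.create(manifest, parents, author, int(ts_str), int(off_str), message)

    @property
    def short_id(self) -> str:
        return self.id[:12]


# -- workspaces --------------------------------------------------------------

_STORE_DIR = ".mrepo"


class Workspace:
    """A repository: object store + changeset DAG + (optional) disk backing.

    A workspace can be purely in-memory (the default, used heavily in tests
    and by the synthetic fixtures) or backed by a directory, in which case
    the store lives under ``<root>/.mrepo`` with a flat ``objects/``
    directory and an append-only ``changelog`` listing changeset ids in
    commit order.  History is append-only: changesets are never mutated or
    removed, and because parents must already exist when a changeset is
    added, the parent graph is acyclic by construction.

    ``worktree`` is the mutable working tree (path -> bytes); ``commit()``
    snapshots it when no explicit tree is given.
    """

    def __init__(self, uri: str, root: str | Path | None = None):
        self.uri = uri
        self.objects: dict[str, bytes] = {}
        self._changesets: dict[str, Changeset] = {}
        self._order: list[str] = []
        self._children: dict[str, set[str]] = {}
        self.worktree: dict[str, bytes] = {}
        self._root = Path(root) if root is not None else None

    # -- construction / persistence ----------------------------------------

    @classmethod
    def init(cls, path: str | Path, uri: str | None = None) -> "Workspace":
        """Create a new on-disk workspace rooted at ``path``."""
        root = Path(path)
        store = root / _STORE_DIR
        if store.exists():
            raise ValidationError(f"workspace already initialised at {root}")
        (store / "objects").mkdir(parents=True)
        ws_uri = uri if uri is not None else root.resolve().name
        (store / "uri").write_text(ws_uri + "\n", encoding="utf-8")
        (store / "changelog").write_text("", encoding="utf-8")
        return cls(ws_uri, root=root)

    @classmethod
    def open(cls, path: str | Path) -> "Workspace":
        """Load an on-disk workspace, verifying store integrity.

        Every changelog entry must parse, re-hash to its recorded id, and
        list only parents recorded earlier in the log -- which rules out
        cycles and missing ancestry in a corrupted store.
        """
        root = Path(path)
        store = root / _STORE_DIR
        if not store.is_dir():
            raise NotFoundError(f"no workspace at {root}")
        uri = (store / "uri").read_text(encoding="utf-8").strip()
        ws = cls(uri, root=root)
        for obj in (store / "objects").iterdir():
            ws.objects[obj.name] = obj.read_bytes()
        for line in (store / "changelog").read_text(encoding="utf-8").splitlines():
            cid = line.strip()
            if not cid:
                continue
            if cid not in ws.objects:
                raise IntegrityError(f"changelog references missing object {cid}")
            cs = Changeset.parse(ws.objects[cid])
            if cs.id != cid:
                raise IntegrityError(f"changeset digest mismatch for {cid}")
            ws._register(cs, persist=False)
        # working tree = plain files under root, excluding the store
        for file in sorted(root.rglob("*")):
            if store in file.parents or file == store or not file.is_file():
                continue
            ws.worktree[file.relative_to(root).as_posix()] = file.read_bytes()
        return ws

    def _persist_object(self, oid: str) -> None:
        if self._root is None:
            return
        target = self._root / _STORE_DIR / "objects" / oid
        if not target.exists():
            target.write_bytes(self.objects[oid])

    def _persist_changelog(self, cid: str) -> None:
        if self._root is None:
            return
        with open(self._root / _STORE_DIR / "changelog", "a", encoding="utf-8") as fh:
            fh.write(cid + "\n")

    def write_worktree(self) -> None:
        """Mirror ``worktree`` onto disk (on-disk workspaces only)."""
        if self._root is None:
            return
        store = self._root / _STORE_DIR
        for file in list(self._root.rglob("*")):
            if store in file.parents or file == store or not file.is_file():
                continue
            if file.relative_to(self._root).as_posix() not in self.worktree:
                file.unlink()
        for path, content in self.worktree.items():
            target = self._root / path
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_bytes(content)

    # -- object store --------------------------------------------------------

    def put_object(self, content: bytes) -> str:
        oid = hash_content(content)
        if oid not in self.objects:
            self.objects[oid] = content
        self._persist_object(oid)
        return oid

    def get_object(self, oid: str) -> bytes:
        try:
            return self.objects[oid]
        except KeyError:
            raise NotFoundError(f"unknown object {oid}") from None

    # -- changeset DAG -------------------------------------------------------

    def __contains__(self, rev: str) -> bool:
        return rev in self._changesets

    def __len__(self) -> int:
        return len(self._changesets)

    def changeset(self, rev: str) -> Changeset:
        try:
            return self._changesets[rev]
        except KeyError:
            raise NotFoundError(f"unknown revision {rev} in workspace {self.uri!r}") from None

    def lookup(self, prefix: str) -> Changeset:
        """Resolve a full id or an unambiguous id prefix."""
        if prefix in self._changesets:
            return self._changesets[prefix]
        matches = [cid for cid in self._changesets if cid.startswith(prefix)]
        if len(matches) == 1:
            return self._changesets[matches[0]]
        if len(matches) > 1:
            raise ValidationError(f"ambiguous revision prefix {prefix!r}")
        raise NotFoundError(f"unknown revision {prefix!r} in workspace {self.uri!r}")

    def changesets(self) -> Iterator[Changeset]:
        """Changesets in append (topological) order."""
        return (self._changesets[cid] for cid in self._order)

    def _register(self, cs: Changeset, persist: bool = True) -> None:
        for parent in cs.parents:
            if parent not in self._changesets:
                raise IntegrityError(
                    f"changeset {cs.short_id} lists unknown parent {parent[:12]}"
                )
        if cs.manifest not in self.objects:
            raise IntegrityError(f"changeset {cs.short_id} references missing manifest")
        for path, oid in Manifest.parse(self.objects[cs.manifest]).entries.items():
            if oid not in self.objects:
                raise IntegrityError(f"manifest entry {path!r} references missing blob")
        self._changesets[cs.id] = cs
        self._order.append(cs.id)
        self._children.setdefault(cs.id, set())
        for parent in cs.parents:
            self._children[parent].add(cs.id)
        if persist:
            self.put_object(cs.serialize())
            self._persist_changelog(cs.id)

    def add_changeset(self, cs: Changeset) -> None:
        """Admit a changeset produced elsewhere (pull); validates identity
        and that all referenced objects and parents are present."""
        if cs.id in self._changesets:
            return
        if hash_content(cs.serialize()) != cs.id:
            raise IntegrityError(f"changeset digest mismatch for {cs.short_id}")
        self._register(cs)

    def commit(
        self,
        tree: Mapping[str, bytes] | None = None,
        *,
        author: str,
        timestamp: int,
        tz_offset: int = 0,
        message: str = "",
        parents: Iterable[str] = (),
    ) -> Changeset:
        """Record a snapshot as a new changeset and return it.

        With ``tree=None`` the current ``worktree`` is committed.  Committing
        identical content/metadata/parents twice yields the identical
        changeset (content addressing), not a duplicate.
        """
        if tree is None:
            tree = dict(self.worktree)
        parent_ids = [str(p) for p in parents]
        if len(parent_ids) > 2:
            raise ValidationError("a changeset may have at most two parents")
        if len(set(parent_ids)) != len(parent_ids):
            raise ValidationError("duplicate parent ids")
        for pid in parent_ids:
            if pid not in self._changesets:
                raise NotFoundError(f"unknown parent revision {pid}")
        entries = {validate_path(p): self.put_object(content) for p, content in tree.items()}
        manifest_id = self.put_object(Manifest(entries).serialize())
        cs = Changeset.create(manifest_id, parent_ids, author, timestamp, tz_offset, message)
        if cs.id in self._changesets:
            return self._changesets[cs.id]
        self._register(cs)
        return cs

    def checkout(self, rev: str) -> dict[str, bytes]:
        """Return the file tree at ``rev``, byte-identical to what was
        committed there."""
        cs = self.changeset(rev)
        manifest = Manifest.parse(self.get_object(cs.manifest))
        return {path: self.get_object(oid) for path, oid in manifest.entries.items()}

    def update(self, rev: str) -> None:
        """Set the working tree to the snapshot at ``rev``."""
        self.worktree = self.checkout(rev)

    def heads(self) -> set[Changeset]:
        """Changesets with no children; more than one signals divergent
        lines of development awaiting a merge."""
        return {
            self._changesets[cid]
            for cid, kids in self._children.items()
            if not kids
        }

    def _topo_rank(self) -> dict[str, int]:
        rank: dict[str, int] = {}
        for cid in self._order:  # parents always precede children here
            cs = self._changesets[cid]
            rank[cid] = 1 + max((rank[p] for p in cs.parents), default=-1)
        return rank

    def log(self) -> list[Changeset]:
        """All changesets, newest first.

        Equal timestamps are broken by topological rank then lexicographic
        id, so the order is total and -- read oldest-first -- a child never
        precedes its parent.
        """
        rank = self._topo_rank()
        oldest_first = sorted(
            self._changesets.values(), key=lambda c: (c.timestamp, rank[c.id], c.id)
        )
        return list(reversed(oldest_first))

    def verify(self) -> None:
        """Re-check store integrity: digests, parent ordering, manifests."""
        seen: set[str] = set()
        for cid in self._order:
            cs = self._changesets[cid]
            if hash_content(cs.serialize()) != cid:
                raise IntegrityError(f"digest mismatch for {cid}")
            for parent in cs.parents:
                if parent not in seen:
                    raise IntegrityError(
                        f"changeset {cid[:12]} precedes its parent {parent[:12]} "
                        "(cycle or truncated history)"
                    )
            self.checkout(cid)
            seen.add(cid)
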