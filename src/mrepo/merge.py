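"""DAG queries, three-way merge, and changeset exchange.

History-aware merging is the point of keeping the revision graph: the merge
base of two revisions is a greatest common ancestor, and merging against it
means changes that have already flowed between lines of development are
never merged twice.  Files are merged line-by-line with a diff3-style
algorithm; conflicts are reported structurally (path plus the three hunks)
rather than written into the files, because a model file with inline
conflict markers would be silently invalid XML.

``outgoing``/``pull`` implement exchange of self-contained changeset
bundles between workspaces; push is pull viewed from the other side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Sequence

from .core import Changeset, Manifest, Workspace, hash_content
from .errors import (
    FastForwardError,
    IntegrityError,
    NoCommonAncestorError,
    NotFoundError,
)

__all__ = [
    "FileConflict",
    "MergeResult",
    "MergeOutcome",
    "ChangeBundle",
    "ancestors",
    "is_ancestor",
    "merge_base",
    "diff3_merge",
    "merge_trees",
    "merge",
    "outgoing",
    "pull",
    "push",
]


# -- ancestry ----------------------------------------------------------------

def ancestors(ws: Workspace, rev: str) -> set[str]:
    """All revisions reachable from ``rev`` via parent links, inclusive."""
    start = ws.changeset(rev)
    seen: set[str] = set()
    stack = [start.id]
    while stack:
        cid = stack.pop()
        if cid in seen:
            continue
        seen.add(cid)
        stack.extend(ws.changeset(cid).parents)
    return seen


def is_ancestor(ws: Workspace, a: str, b: str) -> bool:
    """True iff ``a`` is an ancestor of ``b`` (reflexive)."""
    ws.changeset(a)
    return a in ancestors(ws, b)


def merge_base(ws: Workspace, a: str, b: str) -> str:
    """A greatest common ancestor of ``a`` and ``b``.

    Among the common ancestors, keep those that are not ancestors of any
    other common ancestor; if several remain (criss-cross histories) pick
    the one with the latest timestamp, then the lexicographically smallest
    id, so the choice is deterministic.
    """
    common = ancestors(ws, a) & ancestors(ws, b)
    if not common:
        raise NoCommonAncestorError(
            f"revisions {a[:12]} and {b[:12]} share no common ancestor"
        )
    dominated: set[str] = set()
    for cid in common:
        dominated |= ancestors(ws, cid) - {cid}
    maximal = common - dominated
    return sorted(maximal, key=lambda cid: (-ws.changeset(cid).timestamp, cid))[0]


# -- file-level three-way merge ---------------------------------------------

@dataclass(frozen=True)
class FileConflict:
    """One conflicted region: the base text and both competing rewrites."""

    path: str
    base_hunk: bytes
    ours_hunk: bytes
    theirs_hunk: bytes


@dataclass
class MergeResult:
    """Outcome of a (file or tree) three-way merge.

    ``status`` is ``"clean"`` with ``merged_tree`` populated, or
    ``"conflict"`` with the conflict list populated; never both.
    """

    status: str
    merged_tree: dict[str, bytes] | None = None
    conflicts: list[FileConflict] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return self.status == "clean"


def _hunks(base: Sequence[str], other: Sequence[str]) -> list[tuple[int, int, int, int]]:
    """Non-equal opcode regions of a two-way diff, as (b_lo, b_hi, o_lo, o_hi)."""
    sm = SequenceMatcher(a=base, b=other, autojunk=False)
    return [
        (b_lo, b_hi, o_lo, o_hi)
        for tag, b_lo, b_hi, o_lo, o_hi in sm.get_opcodes()
        if tag != "equal"
    ]


def _touch(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    # Closed-interval overlap: adjacent hunks with no stable line between
    # them belong to the same region, as in classic diff3.
    return lo1 <= hi2 and lo2 <= hi1


def diff3_merge(base: bytes, ours: bytes, theirs: bytes, path: str = "<file>") -> MergeResult:
    """Line-based three-way merge of a single file.

    Regions changed on one side only are taken from that side; identical
    changes on both sides collapse; overlapping differing changes become a
    conflict.  Content that does not decode as UTF-8 is treated as opaque:
    it merges only if at most one side changed it or both made the same
    change.
    """
    try:
        base_lines = base.decode("utf-8").splitlines(keepends=True)
        ours_lines = ours.decode("utf-8").splitlines(keepends=True)
        theirs_lines = theirs.decode("utf-8").splitlines(keepends=True)
    except UnicodeDecodeError:
        if ours == theirs or theirs == base:
            return MergeResult("clean", {path: ours})
        if ours == base:
            return MergeResult("clean", {path: theirs})
        return MergeResult("conflict", conflicts=[FileConflict(path, base, ours, theirs)])

    ours_hunks = _hunks(base_lines, ours_lines)
    theirs_hunks = _hunks(base_lines, theirs_lines)

    # Group hunks from either side into regions that overlap (or touch) in
    # base coordinates; between regions the base is unchanged on both sides.
    tagged = sorted(
        [(h, "ours") for h in ours_hunks] + [(h, "theirs") for h in theirs_hunks],
        key=lambda item: (item[0][0], item[0][1]),
    )
    regions: list[tuple[int, int]] = []
    for (b_lo, b_hi, _, _), _side in tagged:
        if regions and _touch(regions[-1][0], regions[-1][1], b_lo, b_hi):
            regions[-1] = (regions[-1][0], max(regions[-1][1], b_hi))
        else:
            regions.append((b_lo, b_hi))

    def side_map(hunks: list[tuple[int, int, int, int]]):
        # Map a base region boundary to the other side's coordinates.  At a
        # region start only hunks strictly before the boundary count (a
        # zero-width insertion AT the boundary belongs to the region); at a
        # region end hunks ending exactly on the boundary belong inside.
        def to_other(pos: int, at_end: bool) -> int:
            delta = 0
            for b_lo, b_hi, o_lo, o_hi in hunks:
                if b_hi < pos or (at_end and b_hi <= pos):
                    delta += (o_hi - o_lo) - (b_hi - b_lo)
                elif b_lo > pos:
                    break
            return pos + delta

        return to_other

    ours_at = side_map(ours_hunks)
    theirs_at = side_map(theirs_hunks)

    merged: list[str] = []
    conflicts: list[FileConflict] = []
    cursor = 0
    for b_lo, b_hi in regions:
        merged.extend(base_lines[cursor:b_lo])
        base_seg = base_lines[b_lo:b_hi]
        ours_seg = ours_lines[ours_at(b_lo, False):ours_at(b_hi, True)]
        theirs_seg = theirs_lines[theirs_at(b_lo, False):theirs_at(b_hi, True)]
        if ours_seg == base_seg:
            merged.extend(theirs_seg)
        elif theirs_seg == base_seg or ours_seg == theirs_seg:
            merged.extend(ours_seg)
        else:
            conflicts.append(
                FileConflict(
                    path,
                    "".join(base_seg).encode("utf-8"),
                    "".join(ours_seg).encode("utf-8"),
                    "".join(theirs_seg).encode("utf-8"),
                )
            )
        cursor = b_hi
    merged.extend(base_lines[cursor:])

    if conflicts:
        return MergeResult("conflict", conflicts=conflicts)
    return MergeResult("clean", {path: "".join(merged).encode("utf-8")})


# -- tree-level merge --------------------------------------------------------

_DELETED = object()


def merge_trees(
    base: dict[str, bytes], ours: dict[str, bytes], theirs: dict[str, bytes]
) -> MergeResult:
    """Three-way merge of whole file trees, file by file.

    Rules for additions/deletions: a file added on one side is kept; added
    on both sides with different content conflicts; deleted on one side and
    modified on the other conflicts (the safe choice for model files).
    """
    merged: dict[str, bytes] = {}
    conflicts: list[FileConflict] = []
    for path in sorted(set(base) | set(ours) | set(theirs)):
        b, o, t = base.get(path), ours.get(path), theirs.get(path)
        if o is not None and t is not None:
            if o == t:
                merged[path] = o
            elif b is None:
                conflicts.append(FileConflict(path, b"", o, t))
            elif o == b:
                merged[path] = t
            elif t == b:
                merged[path] = o
            else:
                result = diff3_merge(b, o, t, path)
                if result.is_clean:
                    merged[path] = result.merged_tree[path]
                else:
                    conflicts.extend(result.conflicts)
        elif o is None and t is None:
            continue  # deleted on both sides (or never existed)
        else:
            survivor = o if o is not None else t
            if b is None:
                merged[path] = survivor  # added on one side
            elif survivor == b:
                pass  # unchanged on one side, deleted on the other
            else:
                conflicts.append(
                    FileConflict(path, b, o if o is not None else b"", t if t is not None else b"")
                )
    if conflicts:
        return MergeResult("conflict", conflicts=conflicts)
    return MergeResult("clean", merged)


@dataclass
class MergeOutcome:
    """Result of a workspace-level merge.

    ``status`` is ``"merged"`` (a new two-parent changeset was created),
    ``"noop"`` (the other revision is already an ancestor: nothing to
    merge), or ``"conflict"`` (no changeset created; see ``conflicts``).
    """

    status: str
    changeset: Changeset | None = None
    conflicts: list[FileConflict] = field(default_factory=list)


def merge(
    ws: Workspace,
    ours: str,
    theirs: str,
    *,
    author: str,
    timestamp: int,
    tz_offset: int = 0,
    message: str = "",
) -> MergeOutcome:
    """History-aware merge of ``theirs`` into ``ours``.

    If ``theirs`` is already an ancestor of ``ours`` the merge is a no-op:
    those changes have been merged before and are not merged again.  If
    ``ours`` is an ancestor of ``theirs`` there is nothing to reconcile and
    creating a two-parent changeset would fabricate history, so a
    :class:`FastForwardError` instructs the caller to update instead.
    """
    ours_cs, theirs_cs = ws.changeset(ours), ws.changeset(theirs)
    if is_ancestor(ws, theirs_cs.id, ours_cs.id):
        return MergeOutcome("noop")
    if is_ancestor(ws, ours_cs.id, theirs_cs.id):
        raise FastForwardError(
            f"{theirs_cs.short_id} is a descendant of {ours_cs.short_id}; "
            "update to it instead of merging"
        )
    base = merge_base(ws, ours_cs.id, theirs_cs.id)
    result = merge_trees(ws.checkout(base), ws.checkout(ours_cs.id), ws.checkout(theirs_cs.id))
    if not result.is_clean:
        return MergeOutcome("conflict", conflicts=result.conflicts)
    cs = ws.commit(
        result.merged_tree,
        author=author,
        timestamp=timestamp,
        tz_offset=tz_offset,
        message=message,
        parents=[ours_cs.id, theirs_cs.id],
    )
    return MergeOutcome("merged", changeset=cs)


# -- exchange ----------------------------------------------------------------

@dataclass
class ChangeBundle:
    """A self-contained set of changes: changesets in topological order
    (parents before children) plus every blob/manifest they reference."""

    changesets: list[Changeset]
    objects: dict[str, bytes]

    def __len__(self) -> int:
        return len(self.changesets)


def outgoing(src: Workspace, dst: Workspace) -> ChangeBundle:
    """Changesets present in ``src`` and absent from ``dst``, bundled with
    their objects.  Append order in ``src`` is topological already."""
    wanted = [cs for cs in src.changesets() if cs.id not in dst]
    objects: dict[str, bytes] = {}
    for cs in wanted:
        objects[cs.id] = src.get_object(cs.id)
        objects[cs.manifest] = src.get_object(cs.manifest)
        for _path, oid in Manifest.parse(objects[cs.manifest]).entries.items():
            objects[oid] = src.get_object(oid)
    return ChangeBundle(wanted, objects)


def apply_bundle(dst: Workspace, bundle: ChangeBundle) -> set[str]:
    """Apply a bundle atomically; a bundle with missing parents or objects
    leaves ``dst`` untouched."""
    incoming = {cs.id for cs in bundle.changesets}
    for cs in bundle.changesets:
        for parent in cs.parents:
            if parent not in dst and parent not in incoming:
                raise IntegrityError(
                    f"bundle not self-contained: missing parent {parent[:12]}"
                )
        for oid in (cs.manifest,):
            if oid not in bundle.objects and oid not in dst.objects:
                raise IntegrityError(f"bundle missing manifest object {oid[:12]}")
        manifest_data = bundle.objects.get(cs.manifest, dst.objects.get(cs.manifest))
        for path, oid in Manifest.parse(manifest_data).entries.items():
            if oid not in bundle.objects and oid not in dst.objects:
                raise IntegrityError(f"bundle missing blob for {path!r}")
    applied: set[str] = set()
    for oid, data in bundle.objects.items():
        if hash_content(data) != oid:
            raise IntegrityError(f"object digest mismatch for {oid[:12]}")
    for oid, data in bundle.objects.items():
        dst.put_object(data)
    for cs in bundle.changesets:
        if cs.id not in dst:
            dst.add_changeset(cs)
            applied.add(cs.id)
    return applied


def pull(dst: Workspace, src: Workspace) -> set[str]:
    """Copy changesets from ``src`` that ``dst`` lacks; returns the applied
    ids.  Idempotent: a second pull applies nothing.  May create extra
    heads, which a later merge reconciles."""
    return apply_bundle(dst, outgoing(src, dst))


def push(src: Workspace, dst: Workspace) -> set[str]:
    """Push is pull seen from the receiving side."""
    return pull(dst, src)
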