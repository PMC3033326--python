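"""Embedded workspaces (pinned sub-models) and import resolution."""

import pytest

from mrepo import (
    DanglingMountError,
    EmbeddingSpec,
    ImportCycleError,
    MountConflictError,
    NotFoundError,
    PathEscapeError,
    UnresolvedImportError,
    ValidationError,
    Workspace,
    WorkspaceRegistry,
    checkout_recursive,
    embed,
    resolve_imports,
    update_embedded,
)
from mrepo.embedded import EMBEDDED_FILE, STATE_FILE


@pytest.fixture()
def channel_child():
    """A child workspace holding an ion-channel sub-model, two revisions
    with distinct marker bytes."""
    child = Workspace("library/ion-channel")
    rev1 = child.commit({"channel.cellml": b"<model marker='rev1'/>\n"},
                        author="lib", timestamp=10, message="v1")
    rev2 = child.commit({"channel.cellml": b"<model marker='rev2'/>\n"},
                        author="lib", timestamp=20, message="v2", parents=[rev1.id])
    return child, rev1.id, rev2.id


@pytest.fixture()
def registry(channel_child):
    reg = WorkspaceRegistry()
    reg.add(channel_child[0])
    return reg


TOP = b'<?xml version="1.0"?>\n<model><import href="lib/ion_channel/channel.cellml"/></model>\n'


class TestEmbed:
    def test_embed_records_both_tracked_files(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent = Workspace("models/heart")
        parent.worktree = {"top.cellml": TOP}
        spec = embed(parent, "lib/ion_channel", child.uri, rev1, registry)
        assert spec.mounts == {"lib/ion_channel": (child.uri, rev1)}
        assert parent.worktree[EMBEDDED_FILE] == f"lib/ion_channel = {child.uri}\n".encode()
        assert parent.worktree[STATE_FILE] == f"{rev1} lib/ion_channel\n".encode()

    def test_embed_at_existing_file_path_conflicts(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent = Workspace("p")
        parent.worktree = {"lib/ion_channel": b"a plain file"}
        with pytest.raises(MountConflictError):
            embed(parent, "lib/ion_channel", child.uri, rev1, registry)

    def test_embed_overlapping_mounts_conflict(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent = Workspace("p")
        embed(parent, "lib", child.uri, rev1, registry)
        with pytest.raises(MountConflictError):
            embed(parent, "lib/nested", child.uri, rev1, registry)

    def test_embed_unknown_child_revision(self, channel_child, registry):
        child, _, _ = channel_child
        parent = Workspace("p")
        with pytest.raises(NotFoundError):
            embed(parent, "lib/x", child.uri, "00" * 32, registry)

    def test_spec_serialization_round_trips_and_sorts(self):
        spec = EmbeddingSpec({"z/m": ("u2", "bb" * 32), "a/m": ("u1", "aa" * 32)})
        files = spec.to_files()
        assert files[EMBEDDED_FILE].decode().splitlines() == ["a/m = u1", "z/m = u2"]
        assert EmbeddingSpec.from_tree(files).mounts == spec.mounts


class TestUpdateEmbedded:
    def test_update_changes_only_the_state_file(self, channel_child, registry):
        child, rev1, rev2 = channel_child
        parent = Workspace("p")
        parent.worktree = {"top.cellml": TOP}
        embed(parent, "lib/ion_channel", child.uri, rev1, registry)
        embedded_before = parent.worktree[EMBEDDED_FILE]
        top_before = parent.worktree["top.cellml"]
        update_embedded(parent, "lib/ion_channel", rev2, registry)
        assert parent.worktree[EMBEDDED_FILE] == embedded_before
        assert parent.worktree["top.cellml"] == top_before
        assert rev2.encode() in parent.worktree[STATE_FILE]

    def test_update_to_current_pin_is_noop(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent = Workspace("p")
        embed(parent, "m", child.uri, rev1, registry)
        before = dict(parent.worktree)
        update_embedded(parent, "m", rev1, registry)
        assert parent.worktree == before

    def test_update_unknown_mount_or_revision(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent = Workspace("p")
        with pytest.raises(NotFoundError):
            update_embedded(parent, "missing", rev1, registry)
        embed(parent, "m", child.uri, rev1, registry)
        state_before = parent.worktree[STATE_FILE]
        with pytest.raises(NotFoundError):
            update_embedded(parent, "m", "00" * 32, registry)
        assert parent.worktree[STATE_FILE] == state_before


class TestRecursiveCheckout:
    def _pinned_parent(self, channel_child, registry, pin):
        child, _, _ = channel_child
        parent = Workspace("models/heart")
        parent.worktree = {"top.cellml": TOP}
        embed(parent, "lib/ion_channel", child.uri, pin, registry)
        rev = parent.commit(author="m", timestamp=100, message="pin child")
        return parent, rev.id

    def test_pin_stability_after_child_advances(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent, parent_rev = self._pinned_parent(channel_child, registry, rev1)
        child.commit({"channel.cellml": b"<model marker='rev3'/>\n"},
                     author="lib", timestamp=30,
                     parents=[next(iter(child.heads())).id])
        tree = checkout_recursive(parent, parent_rev, registry)
        assert tree["lib/ion_channel/channel.cellml"] == b"<model marker='rev1'/>\n"

    def test_historical_checkout_reproduces_historical_pin(self, channel_child, registry):
        child, rev1, rev2 = channel_child
        parent, old_parent_rev = self._pinned_parent(channel_child, registry, rev1)
        update_embedded(parent, "lib/ion_channel", rev2, registry)
        new_parent_rev = parent.commit(author="m", timestamp=200, message="bump pin",
                                       parents=[old_parent_rev]).id
        old_tree = checkout_recursive(parent, old_parent_rev, registry)
        new_tree = checkout_recursive(parent, new_parent_rev, registry)
        assert old_tree["lib/ion_channel/channel.cellml"] == b"<model marker='rev1'/>\n"
        assert new_tree["lib/ion_channel/channel.cellml"] == b"<model marker='rev2'/>\n"

    def test_no_mounts_equals_plain_checkout(self):
        ws = Workspace("w")
        rev = ws.commit({"f": b"x"}, author="a", timestamp=1)
        assert checkout_recursive(ws, rev.id, WorkspaceRegistry()) == ws.checkout(rev.id)

    def test_deleted_child_workspace_is_a_dangling_mount(self, channel_child, registry):
        child, rev1, _ = channel_child
        parent, parent_rev = self._pinned_parent(channel_child, registry, rev1)
        registry.remove(child.uri)
        with pytest.raises(DanglingMountError) as excinfo:
            checkout_recursive(parent, parent_rev, registry)
        assert "lib/ion_channel" in str(excinfo.value)

    def test_self_embedding_hits_depth_limit(self, registry):
        ws = Workspace("ouroboros")
        rev = ws.commit({"f": b"x"}, author="a", timestamp=1)
        registry.add(ws)
        ws.worktree = ws.checkout(rev.id)
        embed(ws, "again", ws.uri, rev.id, registry)
        rev2 = ws.commit(author="a", timestamp=2, parents=[rev.id])
        # rev2 pins rev (no mounts), fine; re-pin to itself to force recursion
        ws.worktree = ws.checkout(rev2.id)
        update_embedded(ws, "again", rev2.id, registry)
        rev3 = ws.commit(author="a", timestamp=3, parents=[rev2.id])
        ws.worktree = ws.checkout(rev3.id)
        update_embedded(ws, "again", rev3.id, registry)
        rev4 = ws.commit(author="a", timestamp=4, parents=[rev3.id])
        with pytest.raises(ValidationError):
            checkout_recursive(ws, rev4.id, registry, max_depth=2)


class TestResolveImports:
    def test_closure_across_a_mount(self):
        tree = {
            "top.cellml": TOP,
            "lib/ion_channel/channel.cellml": b"<model/>",
        }
        closure = resolve_imports(tree, "top.cellml")
        assert [p for p, _ in closure.files] == ["top.cellml", "lib/ion_channel/channel.cellml"]
        assert closure.edges == [
            ("top.cellml", "lib/ion_channel/channel.cellml", "lib/ion_channel/channel.cellml")
        ]

    def test_relative_uri_equivalence(self):
        direct = {
            "top.xml": b'<m><import href="sub/m.xml"/></m>',
            "sub/m.xml": b"<m/>",
        }
        dotted = {
            "top.xml": b'<m><import href="sub/./m.xml"/></m>',
            "sub/m.xml": b"<m/>",
        }
        assert [p for p, _ in resolve_imports(direct, "top.xml").files] == \
               [p for p, _ in resolve_imports(dotted, "top.xml").files]

    def test_dotdot_resolution_within_tree(self):
        tree = {
            "a/top.xml": b'<m><import href="../b/leaf.xml"/></m>',
            "b/leaf.xml": b"<m/>",
        }
        closure = resolve_imports(tree, "a/top.xml")
        assert closure.edges[0][2] == "b/leaf.xml"

    def test_dangling_href_names_importer_and_href(self):
        tree = {"top.xml": b'<m><import href="missing.xml"/></m>'}
        with pytest.raises(UnresolvedImportError) as excinfo:
            resolve_imports(tree, "top.xml")
        assert "top.xml" in str(excinfo.value) and "missing.xml" in str(excinfo.value)

    def test_cycle_reported_with_its_members(self):
        tree = {
            "a.xml": b'<m><import href="b.xml"/></m>',
            "b.xml": b'<m><import href="a.xml"/></m>',
        }
        with pytest.raises(ImportCycleError) as excinfo:
            resolve_imports(tree, "a.xml")
        assert set(excinfo.value.cycle) == {"a.xml", "b.xml"}

    def test_path_escape_rejected(self):
        tree = {"top.xml": b'<m><import href="../../outside.xml"/></m>'}
        with pytest.raises(PathEscapeError):
            resolve_imports(tree, "top.xml")

    def test_absolute_uri_recorded_but_not_fetched(self):
        tree = {"top.xml": b'<m><import href="https://example.org/m.xml"/></m>'}
        closure = resolve_imports(tree, "top.xml")
        assert closure.edges == [("top.xml", "https://example.org/m.xml", None)]
        assert [p for p, _ in closure.files] == ["top.xml"]

    def test_namespaced_cellml_import_recognised(self):
        tree = {
            "top.cellml": (
                b'<model xmlns="http://www.cellml.org/cellml/1.1#" '
                b'xmlns:xlink="http://www.w3.org/1999/xlink">'
                b'<import xlink:href="parts/gate.cellml"/></model>'
            ),
            "parts/gate.cellml": b"<model/>",
        }
        closure = resolve_imports(tree, "top.cellml")
        assert [p for p, _ in closure.files] == ["top.cellml", "parts/gate.cellml"]

    def test_non_xml_companion_file_is_a_leaf(self):
        tree = {
            "top.xml": b'<m><import href="fig.svg"/></m>',
            "fig.svg": b"\x89not-xml-at-all",
        }
        closure = resolve_imports(tree, "top.xml")
        assert [p for p, _ in closure.files] == ["top.xml", "fig.svg"]

    def test_purity_and_closure_bound(self):
        tree = {
            "top.xml": b'<m><import href="a.xml"/><import href="b.xml"/></m>',
            "a.xml": b'<m><import href="b.xml"/></m>',
            "b.xml": b"<m/>",
            "unreachable.xml": b"<m/>",
        }
        first = resolve_imports(tree, "top.xml")
        second = resolve_imports(tree, "top.xml")
        assert [p for p, _ in first.files] == [p for p, _ in second.files]
        assert first.edges == second.edges
        assert len(first.files) <= len(tree)
        assert "unreachable.xml" not in [p for p, _ in first.files]

    def test_top_must_exist_and_parse(self):
        with pytest.raises(NotFoundError):
            resolve_imports({}, "top.xml")
        with pytest.raises(ValidationError):
            resolve_imports({"top.xml": b"not xml <"}, "top.xml")
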