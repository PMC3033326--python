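"""Pinning a shared sub-model inside a composite model.

An ion-channel model lives in its own workspace and is embedded into a
composite model at a pinned revision, so the composite imports exactly the
version it was built against via a relative URI -- even after the channel
workspace moves on.
"""

from mrepo import (
    Workspace, WorkspaceRegistry, checkout_recursive, embed,
    resolve_imports, update_embedded,
)

channel = Workspace("library/ion-channel")
v1 = channel.commit({"channel.cellml": b"<model conductance='120'/>\n"},
                    author="lib", timestamp=100, message="first release")
registry = WorkspaceRegistry()
registry.add(channel)

heart = Workspace("models/heart")
heart.worktree = {
    "heart.cellml": b"<model><import href='lib/channel/channel.cellml'/></model>\n",
}
embed(heart, "lib/channel", channel.uri, v1.id, registry)
pinned = heart.commit(author="modeller", timestamp=200, message="pin channel v1")
print("tracked pin files now in the heart model's history:")
print(" ", heart.checkout(pinned.id)["EMBEDDED"].decode().strip())

v2 = channel.commit({"channel.cellml": b"<model conductance='150'/>\n"},
                    author="lib", timestamp=300, message="refit conductance",
                    parents=[v1.id])
tree = checkout_recursive(heart, pinned.id, registry)
print("\nafter the channel advances, the recursive checkout still yields the pin:")
print(" ", tree["lib/channel/channel.cellml"].decode().strip())

closure = resolve_imports(tree, "heart.cellml")
print("\nimport closure of heart.cellml:",
      [path for path, _ in closure.files])

update_embedded(heart, "lib/channel", v2.id, registry)
bumped = heart.commit(author="modeller", timestamp=400, message="pin channel v2",
                      parents=[pinned.id])
new = checkout_recursive(heart, bumped.id, registry)["lib/channel/channel.cellml"]
old = checkout_recursive(heart, pinned.id, registry)["lib/channel/channel.cellml"]
print("\nnew pin:", new.decode().strip())
print("historical checkout reproduces the historical pin:", old.decode().strip())
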