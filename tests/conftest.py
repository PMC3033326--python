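"""Shared fixtures and independent oracles.

The random-history builder and the brute-force reachability oracle here
deliberately avoid the library's own DAG helpers: oracles must stay
independent of the code paths they check.
"""

from __future__ import annotations

import random

import pytest

from mrepo import Workspace, build_fig1_fixture


@pytest.fixture()
def fig1():
    """The deterministic five-group worked example (A; B,C; D=merge; E).

    Function-scoped: several tests extend the combined workspace by
    merging, and must not observe each other's changes.
    """
    return build_fig1_fixture()


def brute_force_ancestors(ws: Workspace, rev: str) -> set[str]:
    """Reachability by naive recursion over raw parent links."""
    result: set[str] = set()

    def walk(cid: str) -> None:
        if cid in result:
            return
        result.add(cid)
        for parent in ws.changeset(cid).parents:
            walk(parent)

    walk(rev)
    return result


def brute_force_merge_base(ws: Workspace, a: str, b: str) -> str | None:
    """Enumerate all common ancestors, keep the maximal ones (not an
    ancestor of any other common ancestor), then apply the stated
    tie-break: latest timestamp, then lexicographically smallest id."""
    common = brute_force_ancestors(ws, a) & brute_force_ancestors(ws, b)
    if not common:
        return None
    maximal = [
        c for c in common
        if not any(c != d and c in brute_force_ancestors(ws, d) for d in common)
    ]
    maximal.sort(key=lambda cid: (-ws.changeset(cid).timestamp, cid))
    return maximal[0]


def build_random_history(rng: random.Random, max_nodes: int = 50) -> Workspace:
    """A random DAG-shaped history: each commit takes 1 or 2 random
    existing parents (occasionally starting a disjoint root), with
    timestamps drawn with ties possible to exercise tie-breaking."""
    ws = Workspace(f"random/{rng.randrange(1 << 30)}")
    n = rng.randint(2, max_nodes)
    ids: list[str] = []
    for i in range(n):
        if not ids or rng.random() < 0.05:
            parents: list[str] = []
        elif len(ids) >= 2 and rng.random() < 0.35:
            parents = rng.sample(ids, 2)
        else:
            parents = [rng.choice(ids)]
        cs = ws.commit(
            {"model.xml": f"<model n='{i}'/>".encode()},
            author=f"author-{i % 3}",
            timestamp=rng.randint(0, 20),  # small range: frequent ties
            message=f"commit {i}",
            parents=parents,
        )
        ids.append(cs.id)
    return ws


def random_tree(rng: random.Random, max_files: int = 8) -> dict[str, bytes]:
    """A random file tree with nested paths and occasional binary blobs."""
    names = ["model.cellml", "a/b.xml", "a/c/d.svg", "notes.txt", "x.bin", "deep/p/q/r.xml"]
    tree: dict[str, bytes] = {}
    for _ in range(rng.randint(1, max_files)):
        name = rng.choice(names) + str(rng.randint(0, 99))
        if rng.random() < 0.2:
            content = bytes(rng.getrandbits(8) for _ in range(rng.randint(0, 64)))
        else:
            content = "\n".join(
                f"line {rng.randint(0, 9)}" for _ in range(rng.randint(0, 12))
            ).encode()
        tree[name] = content
    return tree
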