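"""Deterministic worked example: five groups sharing one model's history.

The scenario: group A publishes a model of a cell type; group B improves a
sub-model (an ion-channel file); group C retargets the model to another
cell type; group D combines B's improvement with C's change by merging the
two lines; group E independently fixes the stimulus protocol starting from
A's model.  A flat, history-unaware listing shows five models with no
machine-readable relationship between them; the changeset DAG records that
D merged B and C, and makes merging E's fix into D automatic because E's
change touches a file disjoint from the B/C changes.

The construction exercises real exchange: each group works in its own
workspace and obtains the others' changes by pull, and a combined
workspace finally pulls everything.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Workspace, parse_iso8601
from .merge import merge, pull

__all__ = ["Fig1Fixture", "build_fig1_fixture"]

_MODEL = (
    b'<?xml version="1.0"?>\n'
    b'<model name="cell_type_one">\n'
    b'  <import href="channel.cellml"/>\n'
    b'  <import href="stimulus.cellml"/>\n'
    b"</model>\n"
)
_MODEL_C = _MODEL.replace(b"cell_type_one", b"cell_type_two")
_CHANNEL = b'<?xml version="1.0"?>\n<model name="ion_channel">\n  <gate order="3"/>\n</model>\n'
_CHANNEL_B = _CHANNEL.replace(b'order="3"', b'order="4"')
_STIMULUS = b'<?xml version="1.0"?>\n<model name="stimulus">\n  <pulse amplitude="20"/>\n</model>\n'
_STIMULUS_E = _STIMULUS.replace(b'amplitude="20"', b'amplitude="25"')
_NOTES = b"Hypothetical cell model shared between five groups.\n"


@dataclass
class Fig1Fixture:
    """Per-group workspaces, the combined workspace, and the letter -> id map."""

    workspaces: dict[str, Workspace]
    combined: Workspace
    revisions: dict[str, str]


def _ts(iso: str) -> int:
    return parse_iso8601(iso)[0]


def build_fig1_fixture() -> Fig1Fixture:
    """Build the five-revision history A; B,C children of A; D=merge(B,C);
    E child of A, with fixed authors, dates and contents."""
    ws_a = Workspace("fixture/group-a")
    rev_a = ws_a.commit(
        {
            "model.cellml": _MODEL,
            "channel.cellml": _CHANNEL,
            "stimulus.cellml": _STIMULUS,
            "notes.txt": _NOTES,
        },
        author="Group A",
        timestamp=_ts("2009-07-01T09:00:00+00:00"),
        message="Initial model of cell type one",
    )

    ws_b = Workspace("fixture/group-b")
    pull(ws_b, ws_a)
    tree_b = ws_b.checkout(rev_a.id)
    tree_b["channel.cellml"] = _CHANNEL_B
    rev_b = ws_b.commit(
        tree_b,
        author="Group B",
        timestamp=_ts("2009-07-02T09:00:00+00:00"),
        message="Improve ion channel gating model",
        parents=[rev_a.id],
    )

    ws_c = Workspace("fixture/group-c")
    pull(ws_c, ws_a)
    tree_c = ws_c.checkout(rev_a.id)
    tree_c["model.cellml"] = _MODEL_C
    rev_c = ws_c.commit(
        tree_c,
        author="Group C",
        timestamp=_ts("2009-07-03T09:00:00+00:00"),
        message="Adapt model to a different cell type",
        parents=[rev_a.id],
    )

    ws_d = Workspace("fixture/group-d")
    pull(ws_d, ws_b)
    pull(ws_d, ws_c)
    outcome = merge(
        ws_d,
        rev_b.id,
        rev_c.id,
        author="Group D",
        timestamp=_ts("2009-07-04T09:00:00+00:00"),
        message="Combine B's channel improvement with C's cell type change",
    )
    assert outcome.status == "merged", "fixture merge must be clean"
    rev_d = outcome.changeset

    ws_e = Workspace("fixture/group-e")
    pull(ws_e, ws_a)
    tree_e = ws_e.checkout(rev_a.id)
    tree_e["stimulus.cellml"] = _STIMULUS_E
    rev_e = ws_e.commit(
        tree_e,
        author="Group E",
        timestamp=_ts("2009-07-05T09:00:00+00:00"),
        message="Fix stimulus protocol amplitude",
        parents=[rev_a.id],
    )

    combined = Workspace("fixture/combined")
    pull(combined, ws_d)
    pull(combined, ws_e)

    return Fig1Fixture(
        workspaces={"A": ws_a, "B": ws_b, "C": ws_c, "D": ws_d, "E": ws_e},
        combined=combined,
        revisions={
            "A": rev_a.id,
            "B": rev_b.id,
            "C": rev_c.id,
            "D": rev_d.id,
            "E": rev_e.id,
        },
    )
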