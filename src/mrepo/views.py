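"""User-facing renderings of workspaces and exposures.

Two documents mirror what a casual repository user sees: the workspace
summary (history newest-first, with a link to the exposure of any revision
that has one) and the exposure page (documentation, curation table,
publication reference, and the source workspace + revision it presents).
Rendering is pure -- it never mutates workspace or catalog state -- and the
text form is a straight projection of the JSON form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .core import Workspace, format_iso8601
from .exposures import Exposure, ExposureCatalog

__all__ = [
    "SummaryEntry",
    "WorkspaceSummaryDoc",
    "ExposureDoc",
    "render_workspace_summary",
    "render_exposure",
]

SHORT_ID_LEN = 12  # display-only truncation; JSON always carries full ids


@dataclass(frozen=True)
class SummaryEntry:
    revision: str
    short_id: str
    author: str
    timestamp: int
    tz_offset: int
    message: str
    exposure_ids: tuple[str, ...] = ()


@dataclass
class WorkspaceSummaryDoc:
    """The workspace summary view: all changes, newest first."""

    workspace_uri: str
    entries: list[SummaryEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "workspace_uri": self.workspace_uri,
            "entries": [
                {
                    "revision": e.revision,
                    "short_id": e.short_id,
                    "author": e.author,
                    "date": format_iso8601(e.timestamp, e.tz_offset),
                    "message": e.message,
                    "exposure_ids": list(e.exposure_ids),
                }
                for e in self.entries
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"workspace {self.workspace_uri}"]
        for e in self.entries:
            exposures = f"  [exposure: {', '.join(e.exposure_ids)}]" if e.exposure_ids else ""
            lines.append(
                f"{e.short_id}  {format_iso8601(e.timestamp, e.tz_offset)}  "
                f"{e.author}  {e.message}{exposures}"
            )
        return "\n".join(lines)


@dataclass
class ExposureDoc:
    """The exposure view: the curated pointer plus a link back to its
    workspace and the exact revision it presents."""

    exposure: Exposure
    workspace_uri: str
    revision: str

    def to_dict(self) -> dict:
        doc = self.exposure.to_dict()
        doc["workspace_link"] = self.workspace_uri
        return doc

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        e = self.exposure
        lines = [
            f"exposure {e.id}: {e.title}",
            f"workspace: {self.workspace_uri}",
            f"revision:  {self.revision}",
        ]
        if e.pubmed_id:
            lines.append(f"pubmed:    {e.pubmed_id}")
        if e.documentation:
            lines.append("")
            lines.append(e.documentation)
        if e.curation:
            lines.append("")
            lines.append("curation:")
            lines.extend(f"  {tool}: {status}" for tool, status in sorted(e.curation.items()))
        return "\n".join(lines)


def render_workspace_summary(ws: Workspace, catalog: ExposureCatalog) -> WorkspaceSummaryDoc:
    """One entry per changeset, in the same reverse-chronological total
    order as the workspace log, each carrying the ids of its exposures."""
    by_revision = catalog.exposures_for(ws.uri)
    entries = [
        SummaryEntry(
            revision=cs.id,
            short_id=cs.id[:SHORT_ID_LEN],
            author=cs.author,
            timestamp=cs.timestamp,
            tz_offset=cs.tz_offset,
            message=cs.message,
            exposure_ids=tuple(e.id for e in by_revision.get(cs.id, [])),
        )
        for cs in ws.log()
    ]
    return WorkspaceSummaryDoc(workspace_uri=ws.uri, entries=entries)


def render_exposure(catalog: ExposureCatalog, exposure_id: str, ws: Workspace) -> ExposureDoc:
    """The exposure document; raises not-found for an unknown id."""
    exposure = catalog.get(exposure_id)
    return ExposureDoc(exposure=exposure, workspace_uri=ws.uri, revision=exposure.revision)
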