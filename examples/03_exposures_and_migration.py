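"""Migrating a legacy version series, then curating an exposure.

A model stored as three ordinal versions (the pre-DVCS scheme) becomes a
chain of changesets that preserves each version's date of addition.  A
curator then exposes the peer-reviewed second revision -- not the head --
showing that the advertised version and the latest version are distinct
concepts.
"""

from mrepo import (
    ExposureCatalog, Principal, Version, VersionSeries,
    migrate_linear, render_workspace_summary,
)
from mrepo.core import format_iso8601, parse_iso8601


def at(day):
    return parse_iso8601(f"2008-0{day}-01T12:00:00+00:00")[0]


series = VersionSeries([
    Version({"model.cellml": b"<model iteration='1'/>"}, at(3), 0, "version 1"),
    Version({"model.cellml": b"<model iteration='2'/>"}, at(6), 0, "version 2 (peer reviewed)"),
    Version({"model.cellml": b"<model iteration='3'/>"}, at(9), 0, "version 3"),
])
ws = migrate_linear(series, "ws/legacy-heart", author="migration script")
print("migrated chain (oldest first):")
for cs in reversed(ws.log()):
    print(f"  {cs.short_id}  {format_iso8601(cs.timestamp, cs.tz_offset)}  {cs.message}")

curator = Principal("carol", roles={"curator"})
catalog = ExposureCatalog()
reviewed = [c for c in ws.log() if "peer reviewed" in c.message][0]
exposure = catalog.create_exposure(
    curator, ws, reviewed.id,
    title="Legacy heart model (reviewed version)",
    documentation="The peer-reviewed iteration; version 3 is unchecked.",
    pubmed_id="12345678",
    curation={"opencell": "runs", "cor": "runs"},
)
print(f"\nexposed revision {exposure.revision[:12]} as {exposure.id!r} "
      f"(head is {next(iter(ws.heads())).short_id}: not the advertised version)")

print("\nworkspace summary view (exposure links inline):")
print(render_workspace_summary(ws, catalog).to_text())
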