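"""Five research groups, one model: DAG history and automatic merge.

Builds the worked example in which group A publishes a cell model, B and C
modify it independently, D merges both lines, and E fixes a third file
starting from A.  Prints the combined history, the merge base of the two
heads, and the result of merging E's fix into D's model.
"""

from mrepo import build_fig1_fixture, merge, merge_base

fix = build_fig1_fixture()
ws = fix.combined

print(f"combined workspace holds {len(ws)} model revisions "
      "(what a flat, history-unaware listing would present as 5 separate models)")
print("\nhistory, newest first:")
for cs in ws.log():
    print(f"  {cs.short_id}  {cs.author:8s}  {cs.message}")

heads = sorted(ws.heads(), key=lambda c: c.author)
print(f"\nheads awaiting reconciliation: {[c.author for c in heads]}")

base = merge_base(ws, fix.revisions["D"], fix.revisions["E"])
print(f"merge base of D and E: {base[:12]} (group A's original commit)")

outcome = merge(ws, fix.revisions["D"], fix.revisions["E"],
                author="Group D", timestamp=1246950000,
                message="incorporate E's stimulus fix")
print(f"\nmerge E into D: {outcome.status} -> {outcome.changeset.short_id}")
tree = ws.checkout(outcome.changeset.id)
print("merged model keeps B's channel improvement, C's cell type and E's fix:")
print(" ", tree["channel.cellml"].decode().splitlines()[2].strip())
print(" ", tree["model.cellml"].decode().splitlines()[1].strip())
print(" ", tree["stimulus.cellml"].decode().splitlines()[2].strip())

again = merge(ws, outcome.changeset.id, fix.revisions["E"],
              author="Group D", timestamp=1246960000)
print(f"repeating the merge: {again.status} "
      "(already-merged changes are never merged twice)")
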