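# mrepo — a revision-history-aware repository engine for computational models

Repositories of computational models of biological systems (CellML, SBML,
…) have traditionally stored each model as a linear series of ordinal
versions. That scheme loses exactly the information model reuse depends
on: when an ancestral model is modified by several groups, and one group
later folds another group's improvements into its own variant, a linear
archive shows five unrelated models and a merge collapses into a single
opaque item — there is no machine-readable record of which changes have
already been merged, so every further merge is manual.

`mrepo` is a library (plus a thin `mrepo` CLI) implementing the
repository machinery that fixes this:

- **Changeset DAG** (`mrepo.core`) — a workspace versions a whole file
  tree (model files, SVG figures, companion data) in a content-addressed
  object store; each changeset has 0–2 parents, so history is a directed
  acyclic graph and a merge is an ordinary two-parent changeset.
- **History-aware merge and exchange** (`mrepo.merge`) — greatest-common-
  ancestor merge base, line-based three-way (diff3-style) file merge,
  structural conflict reports (never inline markers, which would corrupt
  XML models), and `pull`/`push` of self-contained changeset bundles
  between workspaces.
- **Embedded workspaces** (`mrepo.embedded`) — mount a shared sub-model
  (say, an ion-channel model) inside a composite model at a *pinned*
  revision, tracked in versioned `EMBEDDED`/`EMBEDDED.state` files, so the
  composite imports exactly the sub-model version it was built against via
  relative URIs; plus import-closure resolution for CellML-1.1-style
  `import href` graphs.
- **Exposures and curation** (`mrepo.exposures`) — authors commit and push
  freely to their own workspaces; only curators create *exposures*:
  immutable, documented pointers to the specific revision worth
  advertising (not necessarily the head). Includes migration of legacy
  linear version series into dated changeset chains.
- **Revision-activity statistics** (`mrepo.stats`) — monthly binning of
  commit timestamps and the multiplicative model of revision rate

  r′ = α + β·d + γ·c′  (r′ = ln r, c′ = ln c),

  fitted by OLS on the log scale, where *r* is revisions/month, *c* is
  contracted curator hours/week and *d* indicates whether the DAG-based
  store was deployed. Simplifying the logs out, r̂ = e^α · c^γ · (e^β)^d:
  e^β is the multiplicative change in revision rate attributable to
  deployment and γ the elasticity with respect to curator hours. A
  synthetic-panel generator (which also emits commit timestamps that bin
  back to the panel) supports parameter-recovery studies.
- **Views** (`mrepo.views`) — the workspace-summary and exposure documents
  as JSON/plain text, mirroring what a repository website presents.

## Worked example

`examples/01_history_and_merge.py` builds the five-group scenario — A's
original model, B's channel improvement, C's cell-type change, D merging B
and C, E's independent stimulus fix — through per-group workspaces
exchanging changes by pull:

```
combined workspace holds 5 model revisions (what a flat, history-unaware listing would present as 5 separate models)

history, newest first:
  8c0688f9082b  Group E   Fix stimulus protocol amplitude
  1a7e3649ef9e  Group D   Combine B's channel improvement with C's cell type change
  857aa912cd5f  Group C   Adapt model to a different cell type
  4c5934dfd30f  Group B   Improve ion channel gating model
  b5ae3b25daed  Group A   Initial model of cell type one

heads awaiting reconciliation: ['Group D', 'Group E']
merge base of D and E: b5ae3b25daed (group A's original commit)

merge E into D: merged -> 022090e061bd
merged model keeps B's channel improvement, C's cell type and E's fix:
  <gate order="4"/>
  <model name="cell_type_two">
  <pulse amplitude="25"/>
repeating the merge: noop (already-merged changes are never merged twice)
```

The two heads D and E share A as merge base, so E's fix (a file B and C
never touched) merges into D automatically; repeating the merge is a
no-op because the DAG records that E's changes are already ancestors of
the merge. The other example scripts cover embedded pins
(`02_embedded_workspaces.py`), migration + exposures
(`03_exposures_and_migration.py`) and the revision-rate model
(`04_revision_activity.py`), e.g.:

```
OLS fit of r' = alpha + beta*d + gamma*c' (true alpha=2.5, beta=1.97, gamma=0.769):
  alpha_hat =  2.563   beta_hat =  2.008 (p = 1.61e-22)   gamma_hat =  0.745

multiplicative restatement  r_hat = 12.977 * c^0.745 * 7.45^d
95% CI for the deployment factor: (6.20, 8.96)
```

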