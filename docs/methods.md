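# Methods

## The versioning model

A *workspace* versions one model (or a few closely related models) as a
whole file tree. Every versioned artefact — file blob, manifest, changeset
record — is stored content-addressed under its SHA-256 digest, and a
changeset id is the digest of a canonical serialization of (manifest id,
parent ids in order, author, date, message). Identifiers are therefore
pure functions of content and ancestry: replaying a history in a fresh
workspace reproduces every id, which is what makes pulling and pushing
bundles of changesets between repositories well defined and idempotent.

History is a DAG: a changeset has 0 parents (a root), 1 parent (an
ordinary edit), or 2 parents (a merge; the first parent is the local
side). More than two parents is rejected — a reconciliation of three or
more lines is expressed as successive pairwise merges, which keeps every
reconciliation step in the record. Because a changeset can only be added
when its parents already exist, and ids are content digests, the graph is
acyclic by construction; on loading an on-disk store, every record is
re-hashed and required to follow its parents, so a hand-corrupted store
claiming cyclic ancestry is rejected.

Canonical serializations are frozen (they define the ids): manifests list
`path\tobject-id` lines in lexicographic byte order of paths; changeset
records are `manifest`, `parent`×, `author`, `date <epoch> <tz-minutes>`
lines, a blank line, then the message, all LF-terminated. Commit dates
carry an explicit timezone offset and are *not* required to be monotone:
migration of legacy archives writes historical dates.

`log` orders changesets newest-first by timestamp, breaking ties by
topological rank and then lexicographic id, so the order is total,
deterministic, and — read oldest-first — never places a child before its
parent.

## Merging

The merge base of two revisions is a greatest common ancestor: a common
ancestor that is not an ancestor of any other common ancestor. Criss-cross
histories can have several; we deterministically pick the one with the
latest timestamp, then the lexicographically smallest id. (Selecting a
single base rather than recursively merging multiple bases is a deliberate
simplification; the recursive strategy is out of scope.)

Files are merged with a classic diff3 scheme built on difflib's
longest-matching-block alignment: the two two-way diffs against the base
are grouped into regions wherever their changed hunks overlap or touch
(no stable line between them); a region changed on one side is taken from
that side, identical changes collapse, and differing overlapping changes
produce a conflict. Conflicts are returned structurally — (path, base
hunk, ours hunk, theirs hunk) — and never written into files, because a
model file with inline conflict markers is silently invalid XML. Content
that does not decode as UTF-8 is opaque: it merges only if at most one
side changed it. Tree-level rules: a file added on one side is kept;
added on both sides with different content conflicts; deleted on one side
and modified on the other conflicts (the safe choice for model files).

Workspace-level merge is history-aware: if the other revision is already
an ancestor, the merge is a no-op (changes are never merged twice); if
the current revision is an ancestor of the other, the merge refuses and
instructs an update, since a two-parent changeset with nothing to
reconcile would fabricate history. A conflicting merge creates no
changeset. Exchange (`outgoing`/`pull`/`push`) moves topologically ordered,
self-contained bundles and validates digests, parents and referenced
objects before touching the destination, so a corrupted bundle leaves it
unchanged.

## Embedded workspaces and imports

A mount pins (child workspace URI, child revision) at a path in the
parent tree, recorded in two tracked files — `EMBEDDED` (`mount = uri`
lines) and `EMBEDDED.state` (`revision mount` lines), UTF-8, LF, sorted
by mount path. Because the pin files are ordinary tracked files, pins are
versioned: recursive checkout of an old parent revision reads the pin
files *at that revision* and reproduces the old sub-model bytes
regardless of how far the child has advanced. Mounts may not overlap each
other or collide with tracked files; recursion depth is capped (default
8) to bound self-embedding constructions.

Import resolution covers the reduced composition subset needed here: any
XML element with local name `import` carrying an attribute with local
name `href`, namespace-agnostic. Relative hrefs resolve against the
importing file's directory with `.`/`..` normalisation; climbing above
the tree root is an error; absolute URIs are recorded as edges but never
fetched. Non-XML targets (SVG figures etc.) are closure leaves. Cycles
are reported with their member paths. Full CellML validation and
component/connection semantics are out of scope.

## Exposures, authorization, migration

Authorization is total and default-deny over two actions: `push` is
allowed to the workspace owner or any curator (granting curators push
everywhere is an interpretation — the alternative, curators pushing only
to owned workspaces, is a one-line policy change); `create_exposure` is
allowed to curators only. An exposure binds (workspace URI, revision) —
head or not — with title, documentation, optional PubMed id and a free
tool→status curation mapping; the binding is immutable and the catalog is
a JSON document outside version control, so curation never perturbs
history. Multiple exposures per revision are allowed; lookups therefore
return lists.

`migrate_linear` replays a legacy ordinal-version series as a single
parent chain, using each version's date of addition as the commit date
and its label as the message. Identical consecutive trees still yield
distinct changesets (ancestry differs), and checkout of the k-th migrated
changeset is byte-identical to the k-th input tree.

## The revision-activity model

Commit instants are binned into calendar months in a configurable
timezone (UTC by default), half-open at month boundaries, with zero
months inside the span reported explicitly. The panel joins revision
counts r with contracted curator hours/week c and the deployment
indicator d (0 strictly before the deployment month, 1 from it on), and
optionally drops listed months — e.g. a migration month whose automated
bulk commits would bias the fit — or restricts to an observation window.

The fitted model is r′ = α + β·d + γ·c′ with r′ = ln r, c′ = ln c,
estimated by ordinary least squares with Gaussian errors on the log
scale. Although such a log-transformed linear equation is sometimes
described as a generalised linear model, OLS on the logged response is
the estimator consistent with that equation; a count GLM (log-link
Poisson) is a different model and is deliberately not implemented.
Inference is standard t-based: two-sided p-values and a 95% t-interval
for β, exp-transformed into an interval for the deployment factor e^β.
Degenerate designs (a single d level, hours collinear with the
intercept, fewer than 4 rows) are errors, as is a retained month with
zero revisions — the log is undefined; a documented pseudocount option
(add a constant before logging) exists but is off by default.

### Synthetic generator and what it shows

`simulate_panel` draws r_m = max(1, round(exp(α + β·d_m + γ·ln c_m +
ε_m))), ε_m ~ N(0, σ²), and emits r_m uniformly spaced timestamps per
month so that binning inverts the generator exactly. The default design
is 39 months (February 2007–April 2010) with the deployment switch at
June 2009, matching the analysis window this engine is meant to support;
curator hours follow a fixed repeating pattern spanning 6–38 h/week,
chosen once to give the log-hours covariate realistic spread (in the
motivating data the hours exist only as a plotted series, never as a
table, so a synthetic stand-in is required). Default noise σ = 0.3 on
the log scale gives month-to-month count variation of roughly ±35%,
comparable to what such monthly commit series exhibit.

The generator matches the estimator's assumptions (log-normal
multiplicative noise, exogenous hours, a clean one-way switch). Passing
recovery tests therefore demonstrates that the estimator and intervals
are implemented correctly, not that the model is adequate for any
particular real repository: real commit series have serial correlation,
holiday dips, and deployment effects that phase in gradually, none of
which the generator emulates. The recovery study (500 synthetic panels at
σ = 0.3 by default) reports mean estimates and empirical 95%-interval
coverage for β; with the integer rounding floor at 1, a sufficiently
large α (≥ ~2) keeps discretisation bias negligible, which is why the
recovery configuration uses α = 2.5.

## Numerical and design choices

- SHA-256 for all content addressing; ids are 64-char lowercase hex.
- Merge-base tie-break: latest timestamp, then smallest id (deterministic
  and checked against brute-force enumeration in the tests).
- diff3 adjacency: changed hunks separated by zero stable lines join one
  region (so adjacent opposing edits conflict rather than interleave).
- Commit timestamps are integer epoch seconds plus an integer minute
  offset; ISO-8601 is the only accepted textual form.
- Problem sizes in the test suite (200 random DAGs of ≤50 nodes for the
  merge-base oracle, 100 random panels/trees, 500-replicate recovery) are
  chosen so the whole suite runs in well under a minute while still
  exercising tie-breaks, criss-cross histories and noisy fits.

## Known limitations

No rename/copy tracking, no delta compression, no recursive multi-base
merge, no network transport (exchange is between locally reachable
stores), no CellML schema validation, and no access control on resolving
embedded mounts (a pin into a private child workspace resolves if the
child store is reachable). The regression module fits monthly aggregates
only; it does not model within-month structure.
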