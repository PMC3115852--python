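# Methods

This note records the model behind `daswriteback`, the design choices
made where the protocol leaves room, and what the test fixtures do and
do not emulate.

## The meta-annotation model

The store treats every community edit as an annotation of an annotation.
Formally, the store is an append-only log of version records keyed by
`(segment_id, feature_id)`; for each key the version numbers form the
contiguous chain `1..n`, and the resolved state of a feature is its
maximal-version record.  Four operations append to the log:

* **create** — version 1 for a brand-new id; on a tombstoned id it
  resurrects the feature at `max + 1`, keeping a single auditable chain
  rather than restarting at 1.
* **update** — requires a live feature; `max + 1`.
* **delete** — a tombstone: action DELETE with a snapshot of the
  previous payload, so a renderer can draw the outline of a deleted
  feature without a second lookup.  Deleting twice, or updating a
  tombstone, is a conflict; the feature must be re-created.
* **rollback to j** — an UPDATE whose payload is copied field-by-field
  from version `j`.  Rolling back *to* a DELETE record is rejected
  (restoring a deletion is what `delete` is for).  History is never
  truncated.

Records are immutable and are never removed; all read operations
(`latest_state`, `deleted_features`, `feature_history`) are defined as
scans over the log, and the test suite checks them against an
independent brute-force scan on randomized edit scripts.

Writers are serialized by a store-level reentrant lock, which is also
held across a whole multi-feature HTTP request so request bodies are
atomic.  This is deliberate: the protocol's concurrency requirement is
that version numbers never collide and attribution is exact, not that
writes scale; an embedded deployment with tens of concurrent curators is
the design point.

### Storage backends

Persistence sits behind a three-method contract (`append`, `records`,
`records_for`).  Two backends ship: an in-memory list (tests, examples)
and an embedded relational store on `sqlite3` with one `version_records`
table and a uniqueness constraint on `(segment_id, feature_id,
version)`.  Payload snapshots are stored as JSON in a single column —
the payload is an opaque value to the storage layer, and this keeps the
schema engine-independent.  The full log can be exported and re-imported
as a stream of DAS GFF documents, one per version, with the version
metadata in NOTE tokens.

## The wire dialect

The package reads and writes DAS 1.6 GFF XML:
`DASGFF/GFF/SEGMENT/FEATURE` with `TYPE` (attributes `id`, `cvId`,
`category`), `METHOD` (`id`, `cvId`), `START`, `END`, `SCORE`,
`ORIENTATION`, `PHASE`, `NOTE*`, `LINK*`.  Conventions fixed here:

* Coordinates are 1-based, fully closed amino-acid intervals;
  non-positional features are encoded `start = end = 0` and skip range
  checks.
* A not-applicable score serializes as the literal `-`; orientation and
  phase default to the protein not-applicable tokens `0` and `-`.
* Output is UTF-8 with an XML declaration, fixed element and attribute
  order, and is byte-deterministic for a given document.
* Unknown child elements are ignored with a logged warning, so the
  parser tolerates dialect extensions.
* `Segment.sequence_length` is emitted as an extra attribute only when
  it differs from `stop`; in the common whole-sequence case the output
  is stock DAS 1.6.

Parsing is strict by default (feature invariants enforced).  The service
and the `validate` CLI parse leniently and push coordinate problems
through the validation layer instead, so a bad submission earns a 400
with a machine-readable issue list (`START_AFTER_END`, `OUT_OF_RANGE`,
`NONPOSITIVE_START`, `MISSING_ID`, `BAD_ENUM`) rather than an opaque
parse failure.

### Version metadata on the wire

DAS GFF has no native slot for version metadata, so responses carry it
in NOTE tokens with a `WRITEBACK:` prefix (`WRITEBACK:VERSION=3`,
`WRITEBACK:ACTION=UPDATE`, `WRITEBACK:USER=alice`,
`WRITEBACK:TIMESTAMP=...`), and a tombstone is marked with the bare
token `WRITEBACK:DELETED`.  The tokens are stripped on decode, so user
payloads round-trip unchanged.  An attribute-based encoding was the
alternative; NOTE tokens were chosen because any existing DAS parser
passes them through untouched.

## The REST mapping

One resource, `/das/writeback/features`; the dispatch table is

| method | query shape | store operation |
|---|---|---|
| GET | `segment` | latest states (tombstones included, flagged) |
| GET | `segment, feature, history=1` | full version chain |
| POST | body | create each feature in the body |
| PUT | body | update each feature in the body |
| PUT | `segment, feature, rollback=j` | rollback |
| DELETE | `segment, feature` | tombstone |

POST=create / PUT=update / DELETE=delete / GET=read follows the
AtomPub/GData convention.  The rollback row is this package's own
extension of the table: rollback sends no payload, so it travels as a
query-shaped PUT, keeping the (method, query-shape) table exhaustive and
exclusive.  Status codes are plain HTTP: 200 success, 400 malformed or
invalid, 401 unauthenticated write, 404 unknown target, 405 unknown
method; no error response ever leaves a record behind.  Credentials are
HTTP Basic over a salted-PBKDF2 user table (10 000 iterations, SHA-256);
reads are anonymous.  Write payloads always travel in the body — DAS
clients historically hit a 256-character URL ceiling, which the client
enforces on outgoing write URLs.

The service core is a transport-independent request/response function
wrapped as a WSGI callable, so it runs under `wsgiref` in the fixtures
and CLI or under any production WSGI server.

## Merge semantics

The match key between an original feature and a writeback state is the
feature id alone within the segment; duplicate ids across sources
resolve to the first source in input order with a logged warning.
`MERGE` replaces the matched feature in place (keeping it on its source
track, with provenance in the state flag) rather than moving it to the
writeback track — side-by-side comparison is what `EXTRA_SOURCE` is for.
The label `writeback` is reserved: an input track so labelled is treated
as the product of a previous merge, which makes the overlay idempotent.
Deleted entries always retain their last payload and a `DELETED` flag;
dropping them is a renderer's decision, not the merge engine's.

## Validation and ontologies

Coordinate acceptance is exactly
`{1 ≤ start ≤ end ≤ L} ∪ {(0, 0)}` — `start = end` is allowed because
single-residue features (e.g. a phosphosite) are legitimate DAS
features, so "start before end" is read as non-strict.  All applicable
issues are reported at once, as data.

Term suggestion is case-insensitive prefix matching on term name or id,
ranked by name, capped at a configurable limit (default 10): the `type`
field searches the Sequence Ontology, the PSI protein-modification
ontology and the BioSapiens annotation vocabulary; `method` searches the
Evidence Code Ontology.  The bundled lists are small curated subsets
(two-column TSV) sufficient for suggestion and fixtures; live ontology
lookup services are out of scope, and custom lists can be supplied by
path in the config.

## Fixtures and what they show

`generate_source_document` draws coordinates uniformly as
`start ≤ end` pairs within the sequence and samples types/methods from
the bundled ontology subsets; `generate_edit_script` emits sessions
whose every step is legal at its point in the replay (it tracks live,
dead and rollback-able versions while generating).  Both are fully
deterministic under their seed.  Defaults — a 300-residue protein,
10 features per source document, 20-step scripts with 3 users — are
sized for a typical protein annotation track.

The generators emulate the *shape* of DAS data, not its biology: real
tracks have clustered, overlapping, length-biased features, correlated
types and much longer proteins.  Passing tests therefore demonstrate
protocol and store correctness — lossless transport, exact version
accounting, merge semantics, access control — not robustness to any
statistical property of real annotation corpora.

The mock federation serves each document and the writeback service on
loopback `wsgiref` servers bound to ephemeral ports, so the client is
exercised over real HTTP with no network or external service.

## Problem sizes

The conformance script and the system-level tests use 100 seeded edit
scripts of 20 steps, 100 randomized merge instances, 100 round-trip
documents, a 12×12 coordinate grid, 20 federation plans and an
8-writer × 25-write concurrent session — sizes at which the brute-force
oracles are still trivially auditable while every code path (including
resurrection and rollback chains) is exercised many times.

## Known limitations

* Per-feature serialization means no cross-feature transactions beyond
  the atomicity of one request body.
* No trust or reputation ranking of users or annotations, and no
  distributed replication of the store.
* The SQLite backend is single-file embedded storage; a server-grade
  engine would sit behind the same three-method contract.
* Authentication is HTTP Basic; transport security is the deployment's
  responsibility (terminate TLS in front of the WSGI server).
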