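# daswriteback

Community writeback for Distributed Annotation System (DAS) protein
annotations: a versioned, append-only annotation store exposed as an HTTP
service speaking DAS GFF XML, plus the client-side machinery — federation
fetch, track merging, validation — that lets a DAS browser read and edit
that store.

## The problem

DAS federates read-only annotation servers: a client asks a reference
server for a protein sequence, then many independent annotation servers
for positional features (domains, modification sites, secondary
structure) on that sequence, and overlays everything as tracks.  DAS has
no write path, so domain experts who spot a wrong or missing annotation
cannot contribute a correction.  The writeback extension adds that path
without ever touching the original sources: a third-party *writeback
server* stores community edits, and every edit is a *meta-annotation* —
an annotation of an annotation.

## The model

The unit of editing is the DAS feature `f` on a segment (protein
accession) `S`: identifier, TYPE (with an ontology `cvId`), METHOD,
1-based closed interval `[start, end]` with
`1 ≤ start ≤ end ≤ L` for a protein of length `L` (or `start = end = 0`
for non-positional features), optional score, notes and links.

Every write on `(S, f)` appends one immutable version record

    v_k = (S, f, k, action ∈ {CREATE, UPDATE, DELETE}, user, t, payload),

with `k` running contiguously from 1.  The current state of a feature is
the record with maximal `k`; the feature is *deleted* iff that record's
action is DELETE (a tombstone that retains the last payload so clients
can render an outline).  Rollback to version `j` appends an UPDATE whose
payload equals `v_j`'s — history is never truncated.  Re-creating a
deleted feature continues the same chain at `max + 1`.

On the wire the protocol is REST over one resource,
`/das/writeback/features`, with the HTTP method carrying the intent:
POST = create, PUT = update (or rollback via
`?segment=S;feature=f;rollback=j`), DELETE = tombstone, GET = read
(`?history=1` for the full chain).  Both directions speak DAS GFF XML;
writes require HTTP Basic credentials, reads do not; multi-feature
bodies are atomic.

Clients fold the writeback view into the original tracks in one of three
reading modes: `DISABLED` (originals only), `EXTRA_SOURCE` (originals
plus one appended writeback track), or `MERGE` (writeback payloads
replace originals in place, keyed by feature id; community-created
features are appended; tombstones are flagged `DELETED`, never dropped).
The writeback endpoint is always queried last, after the reference and
every annotation source.

## Worked example

```python
from daswriteback import AnnotationStore, Feature
import dataclasses

store = AnnotationStore()
f = Feature(feature_id="dom1", type_id="polypeptide_domain",
            type_cvid="SO:0000417", start=10, end=95)
store.create_feature("P12345", f, user_id="alice")                    # v1
store.update_feature("P12345", "dom1", dataclasses.replace(f, end=90),
                     user_id="bob")                                    # v2
store.rollback_feature("P12345", "dom1", target_version=1,
                       user_id="alice")                                # v3
store.delete_feature("P12345", "dom1", user_id="bob")                  # v4
for rec in store.feature_history("P12345", "dom1"):
    print(f"v{rec.version_number}  {rec.action.value:6s}  by {rec.user_id}  "
          f"span {rec.payload.start}-{rec.payload.end}")
```

prints

```
v1  CREATE  by alice  span 10-95
v2  UPDATE  by bob  span 10-90
v3  UPDATE  by alice  span 10-95
v4  DELETE  by bob  span 10-95
```

— one contiguous chain for one feature: the rollback (v3) restored the
v1 span without deleting v2, and the final DELETE kept the payload as a
renderable tombstone.  The `examples/` directory has one narrative
script per capability (document round trip, version history, the HTTP
lifecycle, the three reading modes, a full federation session); each
prints what it computes and says what the numbers mean.

A thin CLI, `daswb`, exposes `serve`, `fetch`, `create`, `update`,
`delete`, `rollback`, `history`, `merge`, `validate` and `fixtures`
subcommands over the same library.

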