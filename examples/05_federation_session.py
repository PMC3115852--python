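"""A complete annotation session against a local federation.

Spins up mock reference, annotation and writeback endpoints on loopback
ports, then runs the client the way a writeback-aware browser would:
fetch everything (writeback strictly last), submit an edit and a
deletion, and re-fetch to see the community view change.
"""

from daswriteback import (AnnotationStore, Feature, UserAccount, UserTable,
                          WritebackClient)
from daswriteback.fixtures import MockFederation, generate_source_document

SEG = "P12345"
sources = [generate_source_document(1, SEG, 300, 3, feature_prefix="sp.f"),
           generate_source_document(2, SEG, 300, 2, feature_prefix="pdb.f")]
users = UserTable([UserAccount.create("alice", "secret")])

with MockFederation(sources, AnnotationStore(), users) as fed:
    client = WritebackClient()
    originals, writeback = client.fetch_annotations(fed.plan, SEG)
    print("query order:", " -> ".join(client.query_log))
    print("original tracks:", [(lbl, len(d.features_for(SEG)))
                               for lbl, d in originals])
    print("writeback states before any edit:", len(writeback))

    wb = fed.plan.writeback_source
    new = Feature(feature_id="alice.site1", type_id="phosphorylation_site",
                  type_cvid="BS:00037", start=42, end=42)
    rec = client.submit("create", SEG, new, ("alice", "secret"), wb,
                        sequence_length=300)
    print(f"\ncreated {rec.feature_id} as version {rec.version_number}")
    rec = client.submit("delete", SEG, "alice.site1", ("alice", "secret"), wb)
    print(f"deleted it at version {rec.version_number} (tombstone)")

    _, writeback = client.fetch_annotations(fed.plan, SEG)
    for state in writeback:
        print(f"writeback now holds {state.feature_id}: "
              f"v{state.latest_version}, deleted={state.deleted}")
# The query log always ends with the writeback endpoint — the client
# only consults the community layer once the full original annotation
# landscape is on screen.  The delete did not erase the feature: the
# writeback still serves it, flagged deleted at version 2.
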