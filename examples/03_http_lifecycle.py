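"""The writeback REST protocol in one session.

The HTTP method carries the intent — POST creates, PUT updates, DELETE
tombstones, GET reads — and every body in either direction is a DAS GFF
document.  Writes require credentials; reads do not.  This script
drives the dispatch layer directly (no sockets needed).
"""

from daswriteback import (AnnotationStore, Feature, FeatureDocument, Segment,
                          UserAccount, UserTable, serialize_document)
from daswriteback.service import WritebackRequest, WritebackService

SEG = "P12345"
users = UserTable([UserAccount.create("alice", "secret", "Alice")])
service = WritebackService(AnnotationStore(), users)


def body(*features):
    seg = Segment(segment_id=SEG, start=1, stop=100)
    return serialize_document(FeatureDocument(segments=((seg, features),)))


f = Feature(feature_id="site1", type_id="phosphorylation_site",
            type_cvid="BS:00037", start=42, end=42)

steps = [
    ("POST   (create, no login)", WritebackRequest("POST", body=body(f))),
    ("POST   (create)", WritebackRequest("POST", body=body(f),
                                         credentials=("alice", "secret"))),
    ("GET    (read, anonymous)", WritebackRequest("GET",
                                                  query={"segment": SEG})),
    ("PUT    (update)", WritebackRequest(
        "PUT", body=body(Feature(feature_id="site1", type_id="site",
                                 start=42, end=43)),
        credentials=("alice", "secret"))),
    ("DELETE (tombstone)", WritebackRequest(
        "DELETE", query={"segment": SEG, "feature": "site1"},
        credentials=("alice", "secret"))),
    ("GET    (history)", WritebackRequest(
        "GET", query={"segment": SEG, "feature": "site1", "history": "1"})),
]
for label, req in steps:
    status, response = service.dispatch_request(req)
    print(f"{label:28s} -> HTTP {status}, {len(response)} bytes")
# The unauthenticated create is refused with 401 before anything is
# stored; the authenticated session then builds the version chain
# v1 CREATE, v2 UPDATE, v3 DELETE that the history response returns.
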