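"""Parse and serialize a DAS GFF feature document.

DAS GFF XML is the wire format of every exchange in this package: the
read responses of annotation servers and both directions of the
writeback protocol.  This script builds a small document, writes it
out, reads it back and shows that the round trip is exact.
"""

from daswriteback import (Feature, FeatureDocument, Segment, parse_document,
                          serialize_document)

segment = Segment(segment_id="P12345", start=1, stop=120)
features = (
    Feature(feature_id="dom1", label="kinase domain",
            type_id="polypeptide_domain", type_cvid="SO:0000417",
            method_id="curator inference", method_cvid="ECO:0000205",
            start=10, end=95),
    Feature(feature_id="site1", label="phosphoserine",
            type_id="phosphorylation_site", type_cvid="BS:00037",
            method_id="experimental evidence", method_cvid="ECO:0000006",
            start=42, end=42, score=0.98),
)
doc = FeatureDocument(segments=((segment, features),))

text = serialize_document(doc)
print(text)
back = parse_document(text)

print("document bytes:        ", len(text))
print("features round-tripped:", len(back.segments[0][1]))
print("exact round trip:      ", back == doc)
# The document above is what a writeback client would POST to create
# these two annotations; an exact round trip means no information is
# invented or lost between the in-memory model and the wire.
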