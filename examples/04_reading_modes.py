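"""The three client reading modes.

A client can ignore the community writeback (DISABLED), show it as one
extra track beside the originals (EXTRA_SOURCE), or overlay it onto the
original tracks in place (MERGE).  Tombstoned features are never
dropped — they stay in the view flagged DELETED so a renderer can draw
a transparent outline.
"""

import datetime

from daswriteback import (Feature, ReadingMode, WritebackState, merge_tracks)
from daswriteback.fixtures import generate_source_document

SEG = "P12345"
NOW = datetime.datetime.now(datetime.timezone.utc)

originals = [("uniprot-mock", generate_source_document(1, SEG, 300, 4))]
ids = [f.feature_id for f in originals[0][1].features_for(SEG)]


def wb(fid, deleted=False, version=2):
    payload = Feature(feature_id=fid, type_id="community edit",
                      start=5, end=50)
    return WritebackState(SEG, fid, payload, deleted, version, "alice", NOW)


# the community edited the first feature, deleted the second and added one
writeback = [wb(ids[0]), wb(ids[1], deleted=True),
             wb("community-new", version=1)]

for mode in ReadingMode:
    ts = merge_tracks(originals, writeback, mode, SEG)
    print(f"\n{mode.value}:")
    for label, entries in ts.tracks:
        summary = ", ".join(f"{f.feature_id}[{st.value}]"
                            for f, st in entries) or "(empty)"
        print(f"  {label:14s} {summary}")
# DISABLED leaves the original track untouched; EXTRA_SOURCE appends a
# 'writeback' track holding all three community states; MERGE replaces
# the edited feature in place (UPDATED), flags the tombstone (DELETED),
# keeps untouched features ORIGINAL, and appends only the brand-new
# feature to the writeback track (CREATED).
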