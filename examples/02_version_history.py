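"""Every edit is an annotation of an annotation.

The store never rewrites anything: create, update, delete and rollback
each append one version record, so the whole curation history of a
feature stays auditable.  Deletion is a tombstone — the feature is
flagged, not removed — and a rollback appends a new version carrying an
old payload rather than truncating the chain.
"""

import dataclasses

from daswriteback import AnnotationStore, Feature

store = AnnotationStore()
SEG = "P12345"

f = Feature(feature_id="dom1", type_id="polypeptide_domain",
            type_cvid="SO:0000417", start=10, end=95)
store.create_feature(SEG, f, user_id="alice")                     # v1
store.update_feature(SEG, "dom1", dataclasses.replace(f, end=90),
                     user_id="bob")                               # v2
store.rollback_feature(SEG, "dom1", target_version=1, user_id="alice")  # v3
store.delete_feature(SEG, "dom1", user_id="bob")                  # v4

for rec in store.feature_history(SEG, "dom1"):
    print(f"v{rec.version_number}  {rec.action.value:6s}  by {rec.user_id}  "
          f"span {rec.payload.start}-{rec.payload.end}")

(state,) = store.latest_state(SEG, include_deleted=True)
print("\nlatest version:", state.latest_version,
      "| deleted:", state.deleted,
      "| records kept:", store.record_count())
# Four records for one feature: the chain v1..v4 is contiguous, the
# rollback (v3) restored the v1 span 10-95, and the delete (v4) kept
# that payload as a renderable tombstone outline.
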