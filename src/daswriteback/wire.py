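"""Encoding of writeback metadata on the wire.

The protocol's only payload format is the DAS GFF feature document, which
has no native slot for version metadata.  This module fixes the
convention: action, version number, author and timestamp ride in NOTE
elements with a ``WRITEBACK:`` prefix, and a tombstone is marked with the
bare token ``WRITEBACK:DELETED``.  Ordinary user notes pass through
untouched; the prefixed tokens are stripped again on decode, so a
round-trip through the wire leaves the user payload intact.
"""

from __future__ import annotations

import datetime
import json

from .dasgff import (Feature, FeatureDocument, Segment, parse_document,
                     serialize_document)
from .store import Action, VersionRecord, WritebackState

DELETED_TOKEN = "WRITEBACK:DELETED"
_PREFIX = "WRITEBACK:"


def _meta_notes(*, version: int, action: Action, user: str,
                timestamp: datetime.datetime, deleted: bool) -> list[str]:
    notes = []
    if deleted:
        notes.append(DELETED_TOKEN)
    notes += [
        f"{_PREFIX}VERSION={version}",
        f"{_PREFIX}ACTION={action.value}",
        f"{_PREFIX}USER={user}",
        f"{_PREFIX}TIMESTAMP={timestamp.isoformat()}",
    ]
    return notes


def strip_meta(feature: Feature) -> Feature:
    """Remove all ``WRITEBACK:`` tokens, recovering the user payload."""
    return feature.with_notes(
        n for n in feature.notes if not n.startswith(_PREFIX))


def _read_meta(feature: Feature) -> dict:
    meta: dict = {"deleted": False}
    for n in feature.notes:
        if n == DELETED_TOKEN:
            meta["deleted"] = True
        elif n.startswith(_PREFIX) and "=" in n:
            key, _, value = n[len(_PREFIX):].partition("=")
            meta[key.lower()] = value
    return meta


def annotate_state(state: WritebackState) -> Feature:
    """Feature as served in a GET response: payload + metadata notes."""
    meta = _meta_notes(
        version=state.latest_version,
        action=Action.DELETE if state.deleted else Action.UPDATE,
        user=state.last_user,
        timestamp=state.last_timestamp,
        deleted=state.deleted,
    )
    base = strip_meta(state.latest_payload)
    return base.with_notes(list(base.notes) + meta)


def annotate_record(rec: VersionRecord) -> Feature:
    """Feature as emitted in a history response or the backup log."""
    meta = _meta_notes(
        version=rec.version_number,
        action=rec.action,
        user=rec.user_id,
        timestamp=rec.timestamp,
        deleted=rec.action == Action.DELETE,
    )
    base = strip_meta(rec.payload)
    return base.with_notes(list(base.notes) + meta)


def decode_state(segment_id: str, feature: Feature) -> WritebackState:
    """Inverse of :func:`annotate_state` (client side of a GET)."""
    meta = _read_meta(feature)
    return WritebackState(
        segment_id=segment_id,
        feature_id=feature.feature_id,
        latest_payload=strip_meta(feature),
        deleted=meta["deleted"],
        latest_version=int(meta.get("version", 1)),
        last_user=meta.get("user", ""),
        last_timestamp=_parse_ts(meta.get("timestamp")),
    )


def decode_record(segment_id: str, feature: Feature) -> VersionRecord:
    meta = _read_meta(feature)
    return VersionRecord(
        segment_id=segment_id,
        feature_id=feature.feature_id,
        version_number=int(meta.get("version", 1)),
        action=Action(meta.get("action", "CREATE")),
        user_id=meta.get("user", ""),
        timestamp=_parse_ts(meta.get("timestamp")),
        payload=strip_meta(feature),
    )


def _parse_ts(value: str | None) -> datetime.datetime:
    if not value:
        return datetime.datetime.fromtimestamp(0, datetime.timezone.utc)
    return datetime.datetime.fromisoformat(value)


def parse_document_records(xml_text: str) -> list[VersionRecord]:
    """All version records found in one DAS GFF document."""
    doc = parse_document(xml_text)
    out = []
    for seg, feats in doc.segments:
        for f in feats:
            out.append(decode_record(seg.segment_id, f))
    return out


def states_to_document(segment_id: str, sequence_length: int,
                       states: list[WritebackState],
                       source_href: str = "") -> FeatureDocument:
    seg = Segment(segment_id=segment_id, start=1,
                  stop=max(sequence_length, 1))
    return FeatureDocument(
        source_href=source_href,
        segments=((seg, tuple(annotate_state(s) for s in states)),),
    )


# ---------------------------------------------------------------------------
# JSON snapshot of a Feature (sqlite payload column)


def feature_to_json(f: Feature) -> str:
    return json.dumps({
        "feature_id": f.feature_id,
        "label": f.label,
        "type_id": f.type_id,
        "type_cvid": f.type_cvid,
        "type_category": f.type_category,
        "method_id": f.method_id,
        "method_cvid": f.method_cvid,
        "start": f.start,
        "end": f.end,
        "score": f.score,
        "orientation": f.orientation,
        "phase": f.phase,
        "notes": list(f.notes),
        "links": [list(l) for l in f.links],
    }, sort_keys=True)


def feature_from_json(text: str) -> Feature:
    data = json.loads(text)
    data["notes"] = tuple(data["notes"])
    data["links"] = tuple(tuple(l) for l in data["links"])
    return Feature(**data)
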