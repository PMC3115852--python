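"""Combining original annotation tracks with the community writeback view.

A DAS client shows one track per annotation source.  The writeback store
is just one more source — the last one queried — and the client chooses
how to fold its content into the display.  Three reading modes exist:

* ``DISABLED`` — ignore the writeback entirely; originals pass through
  verbatim.
* ``EXTRA_SOURCE`` — originals pass through verbatim and every writeback
  state appears on one appended ``writeback`` track, so users can compare
  an original annotation side by side with its community edit.
* ``MERGE`` — the writeback overlays the originals in place: an edited
  feature's payload replaces the original (state ``UPDATED``), a
  community-created feature is appended to the writeback track
  (``CREATED``), and a tombstoned feature stays in the track flagged
  ``DELETED`` so a renderer can draw it as a transparent outline.

The track label ``writeback`` is reserved: an input track with that label
is taken to be the product of a previous merge, which makes the overlay
idempotent — merging an already-merged view with the same writeback
changes nothing.

This module is renderer-agnostic: deletion is a state flag on the entry,
never an absence, and no drawing happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .dasgff import Feature, FeatureDocument, Segment
from .errors import InputError
from .store import WritebackState

log = logging.getLogger(__name__)

WRITEBACK_TRACK = "writeback"

#: NOTE token prefix recording an entry's provenance state in exported
#: documents (e.g. ``WRITEBACK:STATE=DELETED``).
STATE_NOTE_PREFIX = "WRITEBACK:STATE="


class ReadingMode(str, Enum):
    DISABLED = "DISABLED"
    EXTRA_SOURCE = "EXTRA_SOURCE"
    MERGE = "MERGE"


class EntryState(str, Enum):
    ORIGINAL = "ORIGINAL"
    CREATED = "CREATED"
    UPDATED = "UPDATED"
    DELETED = "DELETED"


@dataclass(frozen=True)
class TrackSet:
    """Merged per-source view: ordered tracks of (feature, state) entries."""

    tracks: tuple[tuple[str, tuple[tuple[Feature, EntryState], ...]], ...]

    def track(self, source_label: str) -> tuple[tuple[Feature, EntryState], ...]:
        for label, entries in self.tracks:
            if label == source_label:
                return entries
        return ()

    def all_entries(self) -> list[tuple[str, Feature, EntryState]]:
        return [(label, f, st)
                for label, entries in self.tracks
                for f, st in entries]


def merge_tracks(originals: list[tuple[str, FeatureDocument]],
                 writeback: list[WritebackState],
                 mode: ReadingMode,
                 segment_id: str) -> TrackSet:
    """Fold writeback states into the original tracks for one segment.

    The match key between an original feature and a writeback state is
    the feature id alone, within the segment.  If two original sources
    carry the same feature id, the first source in input order wins the
    match and a warning is logged.
    """
    mode = ReadingMode(mode)
    for label, doc in originals:
        if doc.segments and not any(
                seg.segment_id == segment_id for seg, _ in doc.segments):
            raise InputError(
                f"source {label!r} does not address segment {segment_id!r}")
    for state in writeback:
        if state.segment_id != segment_id:
            raise InputError(
                f"writeback state for {state.segment_id!r} does not address "
                f"segment {segment_id!r}")

    original_tracks = [
        (label, doc.features_for(segment_id)) for label, doc in originals
    ]

    if mode is ReadingMode.DISABLED:
        return TrackSet(tuple(
            (label, tuple((f, EntryState.ORIGINAL) for f in feats))
            for label, feats in original_tracks))

    wb_entry = lambda s: (s.latest_payload,
                          EntryState.DELETED if s.deleted
                          else EntryState.CREATED)

    if mode is ReadingMode.EXTRA_SOURCE:
        tracks = [
            (label, tuple((f, EntryState.ORIGINAL) for f in feats))
            for label, feats in original_tracks
            if label != WRITEBACK_TRACK
        ]
        tracks.append((WRITEBACK_TRACK,
                       tuple(wb_entry(s) for s in writeback)))
        return TrackSet(tuple(tracks))

    # MERGE: overlay in place, by feature id
    by_id = {s.feature_id: s for s in writeback}
    matched: set[str] = set()
    tracks: list[tuple[str, tuple]] = []
    wb_track_index: int | None = None
    for label, feats in original_tracks:
        entries = []
        on_wb_track = label == WRITEBACK_TRACK
        for f in feats:
            state = by_id.get(f.feature_id)
            if state is None:
                entries.append((f, EntryState.ORIGINAL))
            elif f.feature_id in matched:
                log.warning(
                    "feature id %r appears in several sources; writeback "
                    "matched the first occurrence only", f.feature_id)
                entries.append((f, EntryState.ORIGINAL))
            else:
                matched.add(f.feature_id)
                if state.deleted:
                    entries.append((state.latest_payload, EntryState.DELETED))
                elif on_wb_track:
                    # anything living on the writeback track was community
                    # created, not an edit of a source annotation
                    entries.append((state.latest_payload, EntryState.CREATED))
                else:
                    entries.append((state.latest_payload, EntryState.UPDATED))
        if on_wb_track and wb_track_index is None:
            wb_track_index = len(tracks)
        tracks.append((label, tuple(entries)))
    leftovers = tuple(
        wb_entry(s) for s in writeback if s.feature_id not in matched)
    if wb_track_index is None:
        tracks.append((WRITEBACK_TRACK, leftovers))
    else:
        label, entries = tracks[wb_track_index]
        tracks[wb_track_index] = (label, entries + leftovers)
    return TrackSet(tuple(tracks))


def trackset_to_documents(ts: TrackSet, segment: Segment,
                          with_state_notes: bool = False
                          ) -> list[tuple[str, FeatureDocument]]:
    """One document per track, suitable for re-merging or for export.

    With ``with_state_notes`` each feature gains a
    ``WRITEBACK:STATE=<state>`` NOTE token recording its provenance, the
    form the CLI writes out.
    """
    docs = []
    for label, entries in ts.tracks:
        feats = []
        for f, state in entries:
            if with_state_notes:
                notes = [n for n in f.notes
                         if not n.startswith(STATE_NOTE_PREFIX)]
                notes.append(STATE_NOTE_PREFIX + state.value)
                f = f.with_notes(notes)
            feats.append(f)
        docs.append((label, FeatureDocument(
            segments=((segment, tuple(feats)),))))
    return docs
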