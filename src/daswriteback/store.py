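"""Append-only, versioned annotation store.

The central idea is *meta-annotation*: every community edit is itself an
annotation of an annotation.  The store never mutates or removes a
record — a create, an update, a delete and a rollback each append one
:class:`VersionRecord`, and the version numbers for a given
``(segment_id, feature_id)`` form the contiguous chain ``1..n``.

Deletion is a tombstone: the feature is tagged deleted (the appended
record carries a snapshot of the previous payload so clients can render
an outline) and remains queryable; a later create on the same id
resurrects it, continuing the same chain.

Persistence sits behind the small :class:`StorageBackend` contract with
two implementations: :class:`MemoryBackend` and a :class:`SqliteBackend`
embedded relational file store.  Per-feature writes are serialized by a
store-level lock so concurrent writers never collide on version numbers.
"""

from __future__ import annotations

import contextlib
import datetime
import sqlite3
import threading
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from .dasgff import Feature, FeatureDocument, Segment, serialize_document
from .errors import ConflictError, InvalidTargetError, NotFoundError


class Action(str, Enum):
    CREATE = "CREATE"
    UPDATE = "UPDATE"
    DELETE = "DELETE"


@dataclass(frozen=True)
class VersionRecord:
    """One writeback event on one feature — the meta-annotation.

    ``payload`` is the feature snapshot after the event; for a DELETE it
    is a copy of the previous version's payload (the tombstone outline).
    """

    segment_id: str
    feature_id: str
    version_number: int
    action: Action
    user_id: str
    timestamp: datetime.datetime
    payload: Feature


@dataclass(frozen=True)
class WritebackState:
    """Resolved latest view of one feature: payload + deleted flag."""

    segment_id: str
    feature_id: str
    latest_payload: Feature
    deleted: bool
    latest_version: int
    last_user: str
    last_timestamp: datetime.datetime


# ---------------------------------------------------------------------------
# storage contract


class StorageBackend:
    """Minimal append/scan contract; engines only need these three calls."""

    def append(self, record: VersionRecord) -> None:
        raise NotImplementedError

    def records(self) -> Iterator[VersionRecord]:
        """All records, in append order."""
        raise NotImplementedError

    def records_for(self, segment_id: str, feature_id: str | None = None
                    ) -> list[VersionRecord]:
        out = [
            r for r in self.records()
            if r.segment_id == segment_id
            and (feature_id is None or r.feature_id == feature_id)
        ]
        return out


class MemoryBackend(StorageBackend):
    def __init__(self):
        self._records: list[VersionRecord] = []

    def append(self, record: VersionRecord) -> None:
        self._records.append(record)

    def records(self) -> Iterator[VersionRecord]:
        return iter(list(self._records))


class SqliteBackend(StorageBackend):
    """Embedded relational file store (single table of version records)."""

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS version_records (
        seq        INTEGER PRIMARY KEY AUTOINCREMENT,
        segment_id TEXT NOT NULL,
        feature_id TEXT NOT NULL,
        version    INTEGER NOT NULL,
        action     TEXT NOT NULL,
        user_id    TEXT NOT NULL,
        timestamp  TEXT NOT NULL,
        payload    TEXT NOT NULL,
        UNIQUE (segment_id, feature_id, version)
    )
    """

    def __init__(self, path: str):
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._conn.execute(self._SCHEMA)
        self._conn.commit()
        self._lock = threading.Lock()

    def append(self, record: VersionRecord) -> None:
        from .wire import feature_to_json, feature_from_json  # local, no cycle at import

        with self._lock:
            self._conn.execute(
                "INSERT INTO version_records "
                "(segment_id, feature_id, version, action, user_id, timestamp, payload) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    record.segment_id,
                    record.feature_id,
                    record.version_number,
                    record.action.value,
                    record.user_id,
                    record.timestamp.isoformat(),
                    feature_to_json(record.payload),
                ),
            )
            self._conn.commit()

    def records(self) -> Iterator[VersionRecord]:
        from .wire import feature_from_json

        with self._lock:
            rows = self._conn.execute(
                "SELECT segment_id, feature_id, version, action, user_id, "
                "timestamp, payload FROM version_records ORDER BY seq"
            ).fetchall()
        for seg, fid, ver, action, user, ts, payload in rows:
            yield VersionRecord(
                segment_id=seg,
                feature_id=fid,
                version_number=ver,
                action=Action(action),
                user_id=user,
                timestamp=datetime.datetime.fromisoformat(ts),
                payload=feature_from_json(payload),
            )

    def close(self) -> None:
        self._conn.close()


# ---------------------------------------------------------------------------
# the store


def _utcnow() -> datetime.datetime:
    return datetime.datetime.now(datetime.timezone.utc)


class AnnotationStore:
    """Versioned store keyed by ``(segment_id, feature_id)``.

    All writes append; reads resolve the record with the highest version
    number per feature.  A reentrant lock serializes writers (and can be
    held across a multi-feature request for atomicity).
    """

    def __init__(self, backend: StorageBackend | None = None,
                 clock=_utcnow):
        self.backend = backend if backend is not None else MemoryBackend()
        self._lock = threading.RLock()
        self._clock = clock

    @contextlib.contextmanager
    def locked(self):
        """Hold the write lock across several operations (atomic request)."""
        with self._lock:
            yield self

    # -- internals ----------------------------------------------------------

    def _chain(self, segment_id: str, feature_id: str) -> list[VersionRecord]:
        recs = self.backend.records_for(segment_id, feature_id)
        recs.sort(key=lambda r: r.version_number)
        return recs

    def _append(self, segment_id, feature_id, version, action, user_id,
                payload) -> VersionRecord:
        rec = VersionRecord(
            segment_id=segment_id,
            feature_id=feature_id,
            version_number=version,
            action=action,
            user_id=user_id,
            timestamp=self._clock(),
            payload=payload,
        )
        self.backend.append(rec)
        return rec

    # -- write operations ---------------------------------------------------

    def create_feature(self, segment_id: str, payload: Feature,
                       user_id: str) -> VersionRecord:
        """Append a CREATE.  Version 1 for a brand-new id; a create on a
        deleted id resurrects it at ``max + 1`` (one auditable chain)."""
        payload.check()
        with self._lock:
            chain = self._chain(segment_id, payload.feature_id)
            if chain and chain[-1].action != Action.DELETE:
                raise ConflictError(
                    f"feature {payload.feature_id!r} already exists on "
                    f"segment {segment_id!r} and is not deleted"
                )
            version = chain[-1].version_number + 1 if chain else 1
            return self._append(segment_id, payload.feature_id, version,
                                Action.CREATE, user_id, payload)

    def update_feature(self, segment_id: str, feature_id: str,
                       payload: Feature, user_id: str) -> VersionRecord:
        payload.check()
        with self._lock:
            chain = self._chain(segment_id, feature_id)
            if not chain:
                raise NotFoundError(
                    f"feature {feature_id!r} unknown on segment {segment_id!r}"
                )
            if chain[-1].action == Action.DELETE:
                raise ConflictError(
                    f"feature {feature_id!r} is deleted; re-create it instead "
                    "of updating"
                )
            return self._append(segment_id, feature_id,
                                chain[-1].version_number + 1,
                                Action.UPDATE, user_id, payload)

    def delete_feature(self, segment_id: str, feature_id: str,
                       user_id: str) -> VersionRecord:
        """Tombstone: append a DELETE carrying the prior payload snapshot."""
        with self._lock:
            chain = self._chain(segment_id, feature_id)
            if not chain:
                raise NotFoundError(
                    f"feature {feature_id!r} unknown on segment {segment_id!r}"
                )
            if chain[-1].action == Action.DELETE:
                raise ConflictError(f"feature {feature_id!r} is already deleted")
            return self._append(segment_id, feature_id,
                                chain[-1].version_number + 1,
                                Action.DELETE, user_id, chain[-1].payload)

    def rollback_feature(self, segment_id: str, feature_id: str,
                         target_version: int, user_id: str) -> VersionRecord:
        """Append an UPDATE whose payload equals the target version's.

        History is never truncated; a rollback is just one more version.
        """
        with self._lock:
            chain = self._chain(segment_id, feature_id)
            if not chain:
                raise NotFoundError(
                    f"feature {feature_id!r} unknown on segment {segment_id!r}"
                )
            by_version = {r.version_number: r for r in chain}
            target = by_version.get(target_version)
            if target is None:
                raise NotFoundError(
                    f"feature {feature_id!r} has no version {target_version}"
                )
            if target.action == Action.DELETE:
                raise InvalidTargetError(
                    f"version {target_version} of {feature_id!r} is a deletion "
                    "and cannot be rolled back to"
                )
            return self._append(segment_id, feature_id,
                                chain[-1].version_number + 1,
                                Action.UPDATE, user_id, target.payload)

    # -- read operations ----------------------------------------------------

    def latest_state(self, segment_id: str,
                     include_deleted: bool = False) -> list[WritebackState]:
        """One :class:`WritebackState` per feature ever written on the
        segment (insertion order of first write); unknown segment → []."""
        latest: dict[str, VersionRecord] = {}
        for rec in self.backend.records_for(segment_id):
            cur = latest.get(rec.feature_id)
            if cur is None or rec.version_number > cur.version_number:
                latest[rec.feature_id] = rec
        states = [
            WritebackState(
                segment_id=segment_id,
                feature_id=fid,
                latest_payload=rec.payload,
                deleted=rec.action == Action.DELETE,
                latest_version=rec.version_number,
                last_user=rec.user_id,
                last_timestamp=rec.timestamp,
            )
            for fid, rec in latest.items()
        ]
        if not include_deleted:
            states = [s for s in states if not s.deleted]
        return states

    def feature_history(self, segment_id: str,
                        feature_id: str) -> list[VersionRecord]:
        chain = self._chain(segment_id, feature_id)
        if not chain:
            raise NotFoundError(
                f"feature {feature_id!r} unknown on segment {segment_id!r}"
            )
        return chain

    def deleted_features(self, segment_id: str) -> list[WritebackState]:
        """Exactly the current tombstones on the segment."""
        return [s for s in self.latest_state(segment_id, include_deleted=True)
                if s.deleted]

    def segment_ids(self) -> list[str]:
        seen: list[str] = []
        for rec in self.backend.records():
            if rec.segment_id not in seen:
                seen.append(rec.segment_id)
        return seen

    def record_count(self) -> int:
        return sum(1 for _ in self.backend.records())

    # -- backup export ------------------------------------------------------

    def export_log(self, sequence_lengths: dict[str, int] | None = None
                   ) -> Iterator[str]:
        """Yield one DAS GFF document per version record, in append order.

        Version metadata (action, user, version, timestamp) rides in
        NOTE tokens so the stream is self-describing and re-importable.
        """
        from .wire import annotate_record

        lengths = sequence_lengths or {}
        for rec in self.backend.records():
            length = lengths.get(rec.segment_id,
                                 max(rec.payload.end, 1))
            seg = Segment(segment_id=rec.segment_id, start=1, stop=length)
            doc = FeatureDocument(
                segments=((seg, (annotate_record(rec),)),))
            yield serialize_document(doc)

    def import_log(self, documents: Iterable[str]) -> int:
        """Replay an :meth:`export_log` stream into this (empty) store.

        Returns the number of records imported.  Records are appended
        verbatim — version numbers, users and timestamps are preserved.
        """
        from .wire import parse_document_records

        n = 0
        with self._lock:
            for text in documents:
                for rec in parse_document_records(text):
                    self.backend.append(rec)
                    n += 1
        return n
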