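"""Programmatic DAS writeback client.

Reproduces the behaviour a writeback-aware DAS browser needs behind the
scenes: fetch the reference and every annotation source first, then — and
only then — the writeback server, which is always the last endpoint in
the queue (the user needs the complete annotation landscape before
deciding to edit anything); and submit create/update/delete/rollback
operations with the HTTP method carrying the intent and a DAS GFF
document in the request body.

Write payloads never travel in the URL: DAS clients historically pushed
everything through GET and hit the 256-character URL limit of common
browsers and servers, which a feature document easily exceeds.  The
client enforces that ceiling on its outgoing write URLs.

Create and update payloads are validated locally (same rules as the
server) before any network call; an invalid feature never leaves the
client.
"""

from __future__ import annotations

import base64
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field

from .dasgff import Feature, FeatureDocument, Segment, parse_document, \
    serialize_document
from .errors import DasWritebackError, InputError, ValidationError
from .store import VersionRecord, WritebackState
from .validation import validate_feature
from .wire import decode_state, parse_document_records

log = logging.getLogger(__name__)

MAX_WRITE_URL = 256


@dataclass(frozen=True)
class Endpoint:
    label: str
    url: str


@dataclass
class FederationPlan:
    """The fixed query plan of one annotation session.

    The registry-discovery step of a live DAS session is replaced by this
    explicit plan; the writeback endpoint is queried strictly after every
    annotation source has answered or timed out.
    """

    reference_source: Endpoint
    annotation_sources: list[Endpoint] = field(default_factory=list)
    writeback_source: Endpoint | None = None


class HttpError(DasWritebackError):
    def __init__(self, status: int, message: str):
        super().__init__(f"HTTP {status}: {message}")
        self.status = status
        self.server_message = message


class WritebackClient:
    def __init__(self, timeout: float = 10.0):
        self.timeout = timeout
        #: labels in the order endpoints were queried (test/inspection aid)
        self.query_log: list[str] = []

    # -- plumbing -----------------------------------------------------------

    def _http(self, method: str, url: str, body: str | None = None,
              credentials: tuple[str, str] | None = None) -> tuple[int, str]:
        data = body.encode("utf-8") if body is not None else None
        req = urllib.request.Request(url, data=data, method=method)
        if data is not None:
            req.add_header("Content-Type", "text/xml; charset=utf-8")
        if credentials:
            token = base64.b64encode(
                f"{credentials[0]}:{credentials[1]}".encode()).decode()
            req.add_header("Authorization", f"Basic {token}")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, resp.read().decode("utf-8")
        except urllib.error.HTTPError as exc:
            return exc.code, exc.read().decode("utf-8", "replace")

    @staticmethod
    def _features_url(endpoint: Endpoint, **params: str) -> str:
        query = ";".join(f"{k}={v}" for k, v in params.items())
        return f"{endpoint.url}?{query}" if query else endpoint.url

    # -- reading ------------------------------------------------------------

    def fetch_annotations(self, plan: FederationPlan, segment_id: str
                          ) -> tuple[list[tuple[str, FeatureDocument]],
                                     list[WritebackState]]:
        """Query reference, annotation sources in plan order, writeback last.

        An unreachable annotation source is logged and skipped (partial
        result); an unreachable writeback yields the originals with an
        empty writeback list and a warning.
        """
        self.query_log.clear()
        self._fetch_reference(plan, segment_id)
        originals: list[tuple[str, FeatureDocument]] = []
        for src in plan.annotation_sources:
            self.query_log.append(src.label)
            try:
                status, text = self._http(
                    "GET", self._features_url(src, segment=segment_id))
                if status != 200:
                    raise HttpError(status, text)
                originals.append((src.label, parse_document(text)))
            except Exception as exc:
                log.warning("annotation source %s unreachable, skipped: %s",
                            src.label, exc)
        writeback: list[WritebackState] = []
        if plan.writeback_source is not None:
            self.query_log.append(plan.writeback_source.label)
            try:
                status, text = self._http(
                    "GET", self._features_url(plan.writeback_source,
                                              segment=segment_id))
                if status != 200:
                    raise HttpError(status, text)
                doc = parse_document(text)
                for seg, feats in doc.segments:
                    writeback += [decode_state(seg.segment_id, f)
                                  for f in feats]
            except Exception as exc:
                log.warning("writeback source unreachable, reading without "
                            "community annotations: %s", exc)
        return originals, writeback

    def _fetch_reference(self, plan: FederationPlan,
                         segment_id: str) -> int | None:
        """Sequence length from the reference endpoint (or None)."""
        self.query_log.append(plan.reference_source.label)
        try:
            status, text = self._http(
                "GET", self._features_url(plan.reference_source,
                                          segment=segment_id))
            if status != 200:
                raise HttpError(status, text)
            doc = parse_document(text)
            for seg, _ in doc.segments:
                if seg.segment_id == segment_id:
                    return seg.sequence_length
        except Exception as exc:
            log.warning("reference source unreachable: %s", exc)
        return None

    def fetch_history(self, endpoint: Endpoint, segment_id: str,
                      feature_id: str) -> list[VersionRecord]:
        url = self._features_url(endpoint, segment=segment_id,
                                 feature=feature_id, history="1")
        status, text = self._http("GET", url)
        if status != 200:
            raise HttpError(status, text)
        return parse_document_records(text)

    # -- writing ------------------------------------------------------------

    def submit(self, op: str, segment_id: str, feature_or_id,
               credentials: tuple[str, str], endpoint: Endpoint,
               sequence_length: int = 0,
               target_version: int | None = None) -> VersionRecord:
        """Send one write operation; returns the stored version record.

        ``op`` is one of ``create``, ``update``, ``delete``, ``rollback``.
        For create/update, ``feature_or_id`` is a :class:`Feature` that is
        validated locally first — a feature the server would reject for
        coordinate reasons is never sent.  For delete/rollback it is the
        feature id.
        """
        if op in ("create", "update"):
            feature: Feature = feature_or_id
            length = sequence_length or max(feature.end, 1)
            issues = validate_feature(feature, length)
            if issues:
                raise ValidationError(
                    f"feature {feature.feature_id!r} failed local validation; "
                    "nothing was sent", issues=issues)
            seg = Segment(segment_id=segment_id, start=1,
                          stop=max(length, 1))
            body = serialize_document(FeatureDocument(
                segments=((seg, (feature,)),)))
            url = endpoint.url
            method = "POST" if op == "create" else "PUT"
        elif op == "delete":
            url = self._features_url(endpoint, segment=segment_id,
                                     feature=str(feature_or_id))
            body, method = None, "DELETE"
        elif op == "rollback":
            if target_version is None:
                raise InputError("rollback requires target_version")
            url = self._features_url(
                endpoint, segment=segment_id, feature=str(feature_or_id),
                rollback=str(target_version))
            body, method = "", "PUT"
        else:
            raise InputError(f"unknown operation {op!r}")

        if len(url) > MAX_WRITE_URL:
            raise InputError(
                f"write URL exceeds {MAX_WRITE_URL} characters; payloads "
                "must travel in the request body")
        status, text = self._http(method, url, body=body,
                                  credentials=credentials)
        if status >= 400:
            raise HttpError(status, text)
        records = parse_document_records(text)
        if not records:
            raise DasWritebackError("server returned no version record")
        return records[0]
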