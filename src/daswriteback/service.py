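"""HTTP front-end of the writeback store.

The service exposes a single resource, ``/das/writeback/features``, and
maps the four HTTP methods onto the store following the AtomPub/GData
CRUD convention:

=======  ==========================================  =================
method   query shape                                 store operation
=======  ==========================================  =================
GET      ``segment``                                 latest_state
GET      ``segment``, ``feature``, ``history=1``     feature_history
POST     body (DAS GFF)                              create_feature
PUT      body (DAS GFF)                              update_feature
PUT      ``segment``, ``feature``, ``rollback=N``    rollback_feature
DELETE   ``segment``, ``feature``                    delete_feature
=======  ==========================================  =================

Both request and response bodies are DAS GFF XML; plain HTTP status
codes (200/400/401/404/405/500) signal success or failure.  Reads are
anonymous; every write requires HTTP Basic credentials checked against a
salted-hash user table.  Multi-feature write bodies are atomic: either
every feature in the document is applied or none is.  Write payloads
always travel in the request body, never the URL — DAS clients histori-
cally ran against a 256-character URL limit, which a feature document
easily exceeds.

The core is a transport-independent :func:`WritebackService.dispatch_request`
over a :class:`WritebackRequest`; :meth:`WritebackService.wsgi_app` wraps
it as a standard WSGI callable for any WSGI server.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import logging
import secrets
from dataclasses import dataclass, field
from urllib.parse import parse_qsl

from .dasgff import FeatureDocument, parse_document, serialize_document
from .errors import (AuthenticationError, ConflictError, DasWritebackError,
                     InvalidTargetError, NotFoundError, SchemaError,
                     StructuralError, ValidationError)
from .store import Action, AnnotationStore, VersionRecord
from .validation import validate_feature
from .wire import annotate_record, states_to_document, strip_meta

log = logging.getLogger(__name__)

FEATURES_PATH = "/das/writeback/features"


# ---------------------------------------------------------------------------
# user accounts


@dataclass(frozen=True)
class UserAccount:
    """One login; the password is stored only as a salted PBKDF2 digest."""

    login: str
    password_digest: str  # "salt$hexdigest"
    display_name: str = ""

    @staticmethod
    def digest(password: str, salt: str | None = None) -> str:
        salt = salt if salt is not None else secrets.token_hex(8)
        dk = hashlib.pbkdf2_hmac(
            "sha256", password.encode(), salt.encode(), 10_000)
        return f"{salt}${dk.hex()}"

    @classmethod
    def create(cls, login: str, password: str,
               display_name: str = "") -> "UserAccount":
        return cls(login=login, password_digest=cls.digest(password),
                   display_name=display_name)

    def verify(self, password: str) -> bool:
        salt, _, expected = self.password_digest.partition("$")
        candidate = self.digest(password, salt)
        return hmac.compare_digest(candidate, self.password_digest)


class UserTable:
    """Lookup of accounts, loadable from a 3-column TSV config file
    (login, salt$digest, display name)."""

    def __init__(self, accounts: list[UserAccount] = ()):  # type: ignore[assignment]
        self._by_login: dict[str, UserAccount] = {}
        for acc in accounts:
            if acc.login in self._by_login:
                raise ValueError(f"duplicate login {acc.login!r}")
            self._by_login[acc.login] = acc

    @classmethod
    def from_file(cls, path: str) -> "UserTable":
        accounts = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                login, digest = parts[0], parts[1]
                display = parts[2] if len(parts) > 2 else ""
                accounts.append(UserAccount(login, digest, display))
        return cls(accounts)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for acc in self._by_login.values():
                fh.write(f"{acc.login}\t{acc.password_digest}\t"
                         f"{acc.display_name}\n")

    def authenticate(self, credentials: tuple[str, str] | None) -> str:
        """Return the login as user id; raise on any failure."""
        if not credentials or not credentials[0]:
            raise AuthenticationError("credentials required")
        login, password = credentials
        account = self._by_login.get(login)
        if account is None or not account.verify(password):
            raise AuthenticationError("unknown login or wrong password")
        return login


# ---------------------------------------------------------------------------
# requests


@dataclass
class WritebackRequest:
    method: str
    query: dict[str, str] = field(default_factory=dict)
    body: str = ""
    credentials: tuple[str, str] | None = None


_WRITE_METHODS = {"POST", "PUT", "DELETE"}


class WritebackService:
    """Maps REST requests onto an :class:`AnnotationStore`."""

    def __init__(self, store: AnnotationStore, users: UserTable):
        self.store = store
        self.users = users

    # -- dispatch -----------------------------------------------------------

    def dispatch_request(self, req: WritebackRequest) -> tuple[int, str]:
        """Serve one request; returns ``(status_code, body)``.

        No store write ever happens on a request answered with >= 400.
        """
        try:
            return self._dispatch(req)
        except AuthenticationError as exc:
            return self._error(401, req, str(exc))
        except NotFoundError as exc:
            return self._error(404, req, str(exc))
        except (StructuralError, SchemaError, ValidationError, ConflictError,
                InvalidTargetError) as exc:
            body = str(exc)
            issues = getattr(exc, "issues", None)
            if issues:
                body += "\n" + "\n".join(
                    f"{i.code.value} {i.field}: {i.message}" for i in issues)
            return self._error(400, req, body)
        except DasWritebackError as exc:
            return self._error(400, req, str(exc))
        except Exception as exc:  # pragma: no cover - defensive
            log.exception("internal error")
            return self._error(500, req, f"internal error: {exc}")

    def _error(self, status: int, req: WritebackRequest, message: str
               ) -> tuple[int, str]:
        self._log(req, status)
        return status, message

    def _log(self, req: WritebackRequest, status: int) -> None:
        log.info("%s segment=%s feature=%s user=%s -> %d",
                 req.method, req.query.get("segment", "-"),
                 req.query.get("feature", "-"),
                 (req.credentials or ("-",))[0], status)

    def _dispatch(self, req: WritebackRequest) -> tuple[int, str]:
        method = req.method.upper()
        if method not in {"GET"} | _WRITE_METHODS:
            return self._error(405, req, f"method {method} not supported")
        if method == "GET":
            return self._get(req)
        user_id = self.users.authenticate(req.credentials)
        if method == "POST":
            return self._write_body(req, user_id, "create")
        if method == "PUT":
            if "rollback" in req.query:
                return self._rollback(req, user_id)
            return self._write_body(req, user_id, "update")
        return self._delete(req, user_id)

    # -- reads --------------------------------------------------------------

    def _get(self, req: WritebackRequest) -> tuple[int, str]:
        segment = req.query.get("segment")
        if not segment:
            raise SchemaError("GET requires a segment query parameter")
        feature = req.query.get("feature")
        if feature and req.query.get("history") in ("1", "true", "yes"):
            records = self.store.feature_history(segment, feature)
            doc = self._records_document(segment, records)
        else:
            states = self.store.latest_state(segment, include_deleted=True)
            length = self._segment_length(segment)
            doc = states_to_document(segment, length, states,
                                     source_href=FEATURES_PATH)
        self._log(req, 200)
        return 200, serialize_document(doc)

    def _segment_length(self, segment_id: str) -> int:
        ends = [s.latest_payload.end
                for s in self.store.latest_state(segment_id, True)]
        return max(ends + [1])

    def _records_document(self, segment_id: str,
                          records: list[VersionRecord]) -> FeatureDocument:
        from .dasgff import Segment
        length = max([r.payload.end for r in records] + [1])
        seg = Segment(segment_id=segment_id, start=1, stop=length)
        return FeatureDocument(
            source_href=FEATURES_PATH,
            segments=((seg, tuple(annotate_record(r) for r in records)),))

    # -- writes -------------------------------------------------------------

    def _parse_body(self, req: WritebackRequest) -> FeatureDocument:
        if not req.body.strip():
            raise SchemaError(f"{req.method} requires a DAS GFF request body")
        # lenient parse: bad coordinates surface as a 400 issue list from
        # the validator, not as an opaque parse failure
        return parse_document(req.body, strict=False)

    def _write_body(self, req, user_id, op: str) -> tuple[int, str]:
        """Apply one store operation per feature in the body, atomically:
        everything is validated and checked against the current state
        under the store lock before the first record is appended."""
        apply_one = self._create_one if op == "create" else self._update_one
        doc = self._parse_body(req)
        work = []
        for seg, feats in doc.segments:
            for f in feats:
                work.append((seg, strip_meta(f)))
        if not work:
            raise SchemaError("request document contains no features")
        records: list[VersionRecord] = []
        with self.store.locked():
            seen_in_body: set[tuple[str, str]] = set()
            for seg, f in work:
                issues = validate_feature(f, seg.sequence_length)
                if issues:
                    raise ValidationError(
                        f"feature {f.feature_id!r} failed validation",
                        issues=issues)
                key = (seg.segment_id, f.feature_id)
                if op == "create" and key in seen_in_body:
                    raise ConflictError(
                        f"feature {f.feature_id!r} appears twice in one "
                        "create request")
                seen_in_body.add(key)
                apply_one(seg, f, user_id, dry_run=True)
            for seg, f in work:
                records.append(apply_one(seg, f, user_id, dry_run=False))
        self._log(req, 200)
        return 200, serialize_document(
            self._records_document(work[0][0].segment_id, records))

    def _create_one(self, seg, f, user_id, dry_run):
        if dry_run:
            live = {s.feature_id
                    for s in self.store.latest_state(seg.segment_id)}
            if f.feature_id in live:
                raise ConflictError(
                    f"feature {f.feature_id!r} already exists on segment "
                    f"{seg.segment_id!r} and is not deleted")
            return None
        return self.store.create_feature(seg.segment_id, f, user_id)

    def _update_one(self, seg, f, user_id, dry_run):
        if dry_run:
            states = {s.feature_id: s
                      for s in self.store.latest_state(seg.segment_id, True)}
            state = states.get(f.feature_id)
            if state is None:
                raise NotFoundError(
                    f"feature {f.feature_id!r} unknown on segment "
                    f"{seg.segment_id!r}")
            if state.deleted:
                raise ConflictError(
                    f"feature {f.feature_id!r} is deleted; re-create it "
                    "instead of updating")
            return None
        return self.store.update_feature(
            seg.segment_id, f.feature_id, f, user_id)

    def _rollback(self, req, user_id) -> tuple[int, str]:
        segment = req.query.get("segment")
        feature = req.query.get("feature")
        if not segment or not feature:
            raise SchemaError(
                "rollback requires segment and feature query parameters")
        try:
            target = int(req.query["rollback"])
        except ValueError:
            raise SchemaError("rollback version must be an integer")
        rec = self.store.rollback_feature(segment, feature, target, user_id)
        self._log(req, 200)
        return 200, serialize_document(self._records_document(segment, [rec]))

    def _delete(self, req, user_id) -> tuple[int, str]:
        segment = req.query.get("segment")
        feature = req.query.get("feature")
        if not segment or not feature:
            raise SchemaError(
                "DELETE requires segment and feature query parameters")
        rec = self.store.delete_feature(segment, feature, user_id)
        self._log(req, 200)
        return 200, serialize_document(self._records_document(segment, [rec]))

    # -- WSGI ---------------------------------------------------------------

    def wsgi_app(self, environ, start_response):
        path = environ.get("PATH_INFO", "")
        if path != FEATURES_PATH:
            start_response("404 Not Found",
                           [("Content-Type", "text/plain; charset=utf-8")])
            return [b"unknown resource; use " + FEATURES_PATH.encode()]
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        body = environ["wsgi.input"].read(length).decode("utf-8") if length else ""
        req = WritebackRequest(
            method=environ.get("REQUEST_METHOD", "GET"),
            query=dict(parse_qsl(
                environ.get("QUERY_STRING", "").replace(";", "&"))),
            body=body,
            credentials=_basic_credentials(environ.get("HTTP_AUTHORIZATION")),
        )
        status, out = self.dispatch_request(req)
        reason = {200: "OK", 400: "Bad Request", 401: "Unauthorized",
                  404: "Not Found", 405: "Method Not Allowed",
                  500: "Internal Server Error"}.get(status, "Unknown")
        headers = [("Content-Type",
                    "text/xml; charset=utf-8" if status == 200
                    else "text/plain; charset=utf-8")]
        if status == 401:
            headers.append(("WWW-Authenticate",
                            'Basic realm="DAS writeback"'))
        start_response(f"{status} {reason}", headers)
        return [out.encode("utf-8")]


def _basic_credentials(header: str | None) -> tuple[str, str] | None:
    if not header or not header.startswith("Basic "):
        return None
    try:
        decoded = base64.b64decode(header[6:]).decode("utf-8")
    except Exception:
        return None
    login, _, password = decoded.partition(":")
    return (login, password)
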