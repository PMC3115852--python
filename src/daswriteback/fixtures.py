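"""Deterministic test scaffolding: generated documents, edit scripts and
a local mock federation.

Everything other modules need to be exercised offline is produced here:

* :func:`generate_source_document` — a syntactically valid DAS GFF
  document with a given number of features, every one passing
  coordinate validation, types/methods drawn from the bundled ontology
  subsets.  Same seed, same bytes.
* :func:`generate_edit_script` — a replayable session of create/update/
  delete/rollback steps by several users; every step targets a feature
  and version that exist at that point of the replay.
* :class:`MockFederation` / :func:`run_mock_federation` — reference,
  annotation and writeback endpoints served on loopback ports by
  ``wsgiref`` threads, so :class:`~daswriteback.client.WritebackClient`
  can run a full session against real HTTP.

Feature coordinates are drawn uniformly as start <= end pairs within the
sequence; the generators emulate document *shape*, not the biological
distribution of real annotation tracks.
"""

from __future__ import annotations

import random
import threading
from dataclasses import dataclass, field
from wsgiref.simple_server import WSGIRequestHandler, WSGIServer, make_server

from .client import Endpoint, FederationPlan
from .dasgff import Feature, FeatureDocument, Segment, serialize_document
from .errors import InputError
from .service import UserTable, WritebackService
from .store import AnnotationStore
from .validation import load_bundled_ontologies

_ONTOLOGIES = None


def _ontologies():
    global _ONTOLOGIES
    if _ONTOLOGIES is None:
        _ONTOLOGIES = load_bundled_ontologies()
    return _ONTOLOGIES


def _random_feature(rng: random.Random, feature_id: str,
                    sequence_length: int) -> Feature:
    onts = _ontologies()
    type_ont = onts[rng.choice(("SO", "MOD", "BS"))]
    type_id, type_name = rng.choice(type_ont.terms)
    method_id, method_name = rng.choice(onts["ECO"].terms)
    start = rng.randint(1, sequence_length)
    end = rng.randint(start, sequence_length)
    score = None if rng.random() < 0.5 else round(rng.uniform(0, 1), 3)
    notes = tuple(f"note {rng.randint(0, 999)}"
                  for _ in range(rng.randint(0, 2)))
    return Feature(
        feature_id=feature_id,
        label=f"{type_name} {start}-{end}",
        type_id=type_name,
        type_cvid=type_id,
        type_category="inferred from generator",
        method_id=method_name,
        method_cvid=method_id,
        start=start,
        end=end,
        score=score,
        orientation="0",
        phase="-",
        notes=notes,
    )


def generate_source_document(seed: int, segment_id: str = "P12345",
                             sequence_length: int = 300,
                             n_features: int = 10,
                             feature_prefix: str | None = None
                             ) -> FeatureDocument:
    """A valid single-segment document with ``n_features`` features.

    Deterministic under ``seed``: the serialized output is byte-identical
    across calls.  ``feature_prefix`` sets the feature-id stem (default
    ``<segment_id>.f``); give each mock source its own prefix when ids
    must not collide across sources.
    """
    if sequence_length < 1:
        raise InputError("sequence_length must be >= 1")
    if n_features < 0:
        raise InputError("n_features must be >= 0")
    rng = random.Random(seed)
    prefix = feature_prefix if feature_prefix is not None else f"{segment_id}.f"
    feats = tuple(
        _random_feature(rng, f"{prefix}{i + 1}", sequence_length)
        for i in range(n_features))
    seg = Segment(segment_id=segment_id, start=1, stop=sequence_length)
    return FeatureDocument(segments=((seg, feats),))


# ---------------------------------------------------------------------------
# edit scripts


@dataclass(frozen=True)
class EditStep:
    user_id: str
    op: str  # create | update | delete | rollback
    feature: Feature | None = None       # create/update payload
    feature_id: str = ""                 # update/delete/rollback target
    target_version: int = 0              # rollback only


@dataclass(frozen=True)
class EditScript:
    """A replayable annotation session; deterministic under its seed."""

    seed: int
    segment_id: str
    sequence_length: int
    steps: tuple[EditStep, ...] = ()


def generate_edit_script(seed: int, n_steps: int = 20, n_users: int = 3,
                         segment_id: str = "P12345",
                         sequence_length: int = 300) -> EditScript:
    """A script whose every step is legal at its point in the replay.

    Updates and deletes only target live features, rollbacks only target
    non-delete versions that exist; replaying a generated script never
    raises a not-found or conflict error.
    """
    if n_steps < 1:
        raise InputError("n_steps must be >= 1")
    rng = random.Random(seed)
    users = [f"user{i + 1}" for i in range(max(n_users, 1))]
    steps: list[EditStep] = []
    # simulated state: feature id -> (live?, [versions-with-non-delete-action])
    live: dict[str, list[int]] = {}
    dead: dict[str, list[int]] = {}
    next_version: dict[str, int] = {}
    serial = 0

    def new_feature_id() -> str:
        nonlocal serial
        serial += 1
        return f"{segment_id}.wb{serial}"

    for _ in range(n_steps):
        user = rng.choice(users)
        ops = ["create"]
        if live:
            ops += ["update", "update", "delete"]
            if any(live.values()):
                ops.append("rollback")
        op = rng.choice(ops) if steps else "create"
        if op == "create":
            # half the time resurrect a deleted feature
            if dead and rng.random() < 0.5:
                fid = rng.choice(sorted(dead))
                rollforward = dead.pop(fid)
            else:
                fid = new_feature_id()
                rollforward = []
                next_version.setdefault(fid, 0)
            payload = _random_feature(rng, fid, sequence_length)
            next_version[fid] = next_version.get(fid, 0) + 1
            live[fid] = rollforward + [next_version[fid]]
            steps.append(EditStep(user, "create", feature=payload,
                                  feature_id=fid))
        elif op == "update":
            fid = rng.choice(sorted(live))
            payload = _random_feature(rng, fid, sequence_length)
            next_version[fid] += 1
            live[fid].append(next_version[fid])
            steps.append(EditStep(user, "update", feature=payload,
                                  feature_id=fid))
        elif op == "delete":
            fid = rng.choice(sorted(live))
            next_version[fid] += 1
            dead[fid] = live.pop(fid)
            steps.append(EditStep(user, "delete", feature_id=fid))
        else:  # rollback
            candidates = sorted(fid for fid, vs in live.items() if vs)
            fid = rng.choice(candidates)
            target = rng.choice(live[fid])
            next_version[fid] += 1
            live[fid].append(next_version[fid])
            steps.append(EditStep(user, "rollback", feature_id=fid,
                                  target_version=target))
    return EditScript(seed=seed, segment_id=segment_id,
                      sequence_length=sequence_length, steps=tuple(steps))


def replay_script(script: EditScript, store: AnnotationStore) -> None:
    """Apply every step of the script to the store, in order."""
    for step in script.steps:
        if step.op == "create":
            store.create_feature(script.segment_id, step.feature,
                                 step.user_id)
        elif step.op == "update":
            store.update_feature(script.segment_id, step.feature_id,
                                 step.feature, step.user_id)
        elif step.op == "delete":
            store.delete_feature(script.segment_id, step.feature_id,
                                 step.user_id)
        elif step.op == "rollback":
            store.rollback_feature(script.segment_id, step.feature_id,
                                   step.target_version, step.user_id)
        else:  # pragma: no cover - generator never emits others
            raise InputError(f"unknown op {step.op!r}")


# ---------------------------------------------------------------------------
# mock federation


def _static_document_app(doc: FeatureDocument):
    """A WSGI app serving one pre-serialized document for any GET."""
    body = serialize_document(doc).encode("utf-8")

    def app(environ, start_response):
        start_response("200 OK",
                       [("Content-Type", "text/xml; charset=utf-8")])
        return [body]

    return app


class _QuietServer(WSGIServer):
    def handle_error(self, request, client_address):  # pragma: no cover
        pass


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format, *args):  # per-request stderr noise off
        pass


class MockFederation:
    """Reference + annotation + writeback endpoints on loopback ports.

    Usable as a context manager; :meth:`close` shuts every server down
    and leaves no listening sockets behind.
    """

    def __init__(self, sources: list[FeatureDocument],
                 store: AnnotationStore,
                 users: UserTable | None = None):
        self._servers = []
        self._threads = []
        self.users = users if users is not None else UserTable([])
        self.service = WritebackService(store, self.users)

        if sources:
            seg = sources[0].segments[0][0]
            ref_doc = FeatureDocument(segments=((seg, ()),))
        else:
            ref_doc = FeatureDocument()
        ref_url = self._serve(_static_document_app(ref_doc))
        annotation = []
        for i, doc in enumerate(sources):
            url = self._serve(_static_document_app(doc))
            annotation.append(Endpoint(label=f"src{i + 1}", url=url))
        wb_url = self._serve(self.service.wsgi_app,
                             path="/das/writeback/features")
        self.plan = FederationPlan(
            reference_source=Endpoint(label="ref", url=ref_url),
            annotation_sources=annotation,
            writeback_source=Endpoint(label="writeback", url=wb_url),
        )

    def _serve(self, app, path: str = "") -> str:
        try:
            server = make_server("127.0.0.1", 0, app,
                                 server_class=_QuietServer,
                                 handler_class=_QuietHandler)
        except OSError as exc:  # pragma: no cover
            self.close()
            raise InputError(f"could not bind mock endpoint: {exc}") from exc
        thread = threading.Thread(target=server.serve_forever,
                                  kwargs={"poll_interval": 0.05},
                                  daemon=True)
        thread.start()
        self._servers.append(server)
        self._threads.append(thread)
        host, port = server.server_address[:2]
        return f"http://{host}:{port}{path}"

    def close(self) -> None:
        for server in self._servers:
            server.shutdown()
            server.server_close()
        for thread in self._threads:
            thread.join(timeout=5)
        self._servers.clear()
        self._threads.clear()

    def __enter__(self) -> "MockFederation":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def run_mock_federation(sources: list[FeatureDocument],
                        store: AnnotationStore,
                        users: UserTable | None = None) -> MockFederation:
    """Start a local federation; caller is responsible for ``close()``
    (or use the returned object as a context manager)."""
    return MockFederation(sources, store, users)
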