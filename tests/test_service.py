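"""REST dispatch: CRUD mapping, status codes, authentication gating,
atomic multi-feature bodies, and read/write symmetry."""

import pytest

from daswriteback import (Feature, FeatureDocument, Segment, parse_document,
                          serialize_document)
from daswriteback.service import (UserAccount, UserTable, WritebackRequest,
                                  WritebackService)
from daswriteback.wire import DELETED_TOKEN, strip_meta

SEG = "P12345"
ALICE = ("alice", "secret")


def doc_with(*features, stop=100):
    seg = Segment(segment_id=SEG, start=1, stop=stop)
    return serialize_document(FeatureDocument(segments=((seg, features),)))


def feat(fid="f1", start=10, end=20, **kw):
    return Feature(feature_id=fid, type_id="domain", start=start, end=end,
                   **kw)


def get(service, **query):
    return service.dispatch_request(WritebackRequest("GET", query=query))


def post(service, body, credentials=ALICE):
    return service.dispatch_request(
        WritebackRequest("POST", body=body, credentials=credentials))


def put(service, body="", credentials=ALICE, **query):
    return service.dispatch_request(
        WritebackRequest("PUT", query=query, body=body,
                         credentials=credentials))


def delete(service, credentials=ALICE, **query):
    return service.dispatch_request(
        WritebackRequest("DELETE", query=query, credentials=credentials))


class TestAuthentication:
    def test_correct_password_returns_login(self, users):
        assert users.authenticate(ALICE) == "alice"

    @pytest.mark.parametrize("creds", [
        ("alice", "wrong"), ("nobody", "secret"), ("", ""), None,
    ])
    def test_bad_credentials_rejected(self, users, creds):
        from daswriteback.errors import AuthenticationError
        with pytest.raises(AuthenticationError):
            users.authenticate(creds)

    def test_password_never_stored_in_clear(self):
        acc = UserAccount.create("carol", "topsecret")
        assert "topsecret" not in acc.password_digest
        assert acc.verify("topsecret") and not acc.verify("topsecreT")

    def test_user_table_file_round_trip(self, tmp_path, users):
        path = str(tmp_path / "users.tsv")
        users.to_file(path)
        reloaded = UserTable.from_file(path)
        assert reloaded.authenticate(ALICE) == "alice"

    @pytest.mark.parametrize("method", ["POST", "PUT", "DELETE"])
    def test_every_write_without_credentials_is_401(self, service, store,
                                                    method):
        """Writes are gated on login; the store stays untouched."""
        body = doc_with(feat()) if method in ("POST", "PUT") else ""
        query = {"segment": SEG, "feature": "f1"} if method == "DELETE" else {}
        status, _ = service.dispatch_request(
            WritebackRequest(method, query=query, body=body,
                             credentials=None))
        assert status == 401
        assert store.record_count() == 0

    def test_read_requires_no_credentials(self, service):
        status, body = get(service, segment=SEG)
        assert status == 200
        assert parse_document(body).segments[0][0].segment_id == SEG


class TestCrudLifecycle:
    def test_full_lifecycle_status_and_versions(self, service, store):
        """create -> read -> update -> read -> delete -> read with the
        exact codes and version chain of the protocol."""
        status, body = post(service, doc_with(feat()))
        assert status == 200
        assert "VERSION=1" in body
        status, body = get(service, segment=SEG)
        assert status == 200
        (f,) = parse_document(body).segments[0][1]
        assert strip_meta(f) == feat()

        status, body = put(service, doc_with(feat(start=1, end=2)))
        assert status == 200
        assert "VERSION=2" in body
        status, body = get(service, segment=SEG)
        (f,) = parse_document(body).segments[0][1]
        assert strip_meta(f) == feat(start=1, end=2)

        status, body = delete(service, segment=SEG, feature="f1")
        assert status == 200
        assert "VERSION=3" in body
        status, body = get(service, segment=SEG)
        (f,) = parse_document(body).segments[0][1]
        assert DELETED_TOKEN in f.notes

        hist = store.feature_history(SEG, "f1")
        assert [r.version_number for r in hist] == [1, 2, 3]
        assert [r.action.value for r in hist] == ["CREATE", "UPDATE", "DELETE"]

    def test_history_query_returns_all_versions(self, service):
        post(service, doc_with(feat()))
        put(service, doc_with(feat(start=1, end=2)))
        status, body = get(service, segment=SEG, feature="f1", history="1")
        assert status == 200
        feats = parse_document(body).segments[0][1]
        assert len(feats) == 2
        assert [n for f in feats for n in f.notes if "ACTION" in n] == \
            ["WRITEBACK:ACTION=CREATE", "WRITEBACK:ACTION=UPDATE"]

    def test_rollback_via_put_query(self, service, store):
        post(service, doc_with(feat(start=1, end=2)))
        put(service, doc_with(feat(start=5, end=9)))
        status, body = put(service, segment=SEG, feature="f1", rollback="1")
        assert status == 200
        assert "VERSION=3" in body
        (state,) = store.latest_state(SEG)
        assert (state.latest_payload.start, state.latest_payload.end) == (1, 2)

    def test_read_write_symmetry(self, service):
        """A document accepted by POST comes back from GET with the same
        payload, modulo version metadata notes."""
        sent = [feat("a", 1, 5, notes=("mine",)), feat("b", 7, 9)]
        post(service, doc_with(*sent))
        _, body = get(service, segment=SEG)
        got = [strip_meta(f) for f in parse_document(body).segments[0][1]]
        assert got == sent


class TestErrors:
    @pytest.mark.parametrize("method,query,body,expected", [
        ("POST", {}, "<notxml", 400),                       # malformed body
        ("POST", {}, "", 400),                              # empty body
        ("PUT", {}, "", 400),
        ("PUT", {"segment": SEG, "feature": "f1"}, "", 400),  # no rollback key
        ("DELETE", {"segment": SEG, "feature": "ghost"}, "", 404),
        ("PATCH", {}, "", 405),
        ("GET", {}, "", 400),                               # no segment
    ])
    def test_error_codes(self, service, store, method, query, body, expected):
        status, _ = service.dispatch_request(
            WritebackRequest(method, query=query, body=body,
                             credentials=ALICE))
        assert status == expected
        assert store.record_count() == 0

    def test_update_of_unknown_feature_is_404(self, service):
        status, _ = put(service, doc_with(feat("ghost")))
        assert status == 404

    def test_create_conflict_is_400(self, service, store):
        post(service, doc_with(feat()))
        status, _ = post(service, doc_with(feat()))
        assert status == 400
        assert store.record_count() == 1

    def test_validation_failure_lists_issues(self, service, store):
        # build a start>end body by swapping coordinates in valid XML
        body = doc_with(feat()).replace(
            "<START>10</START>", "<START>50</START>").replace(
            "<END>20</END>", "<END>10</END>")
        status, response = post(service, body)
        assert status == 400
        assert "START_AFTER_END" in response
        assert store.record_count() == 0

    def test_out_of_range_checked_against_segment_length(self, service):
        status, body = post(service, doc_with(feat(start=90, end=150),
                                              stop=100))
        assert status == 400
        assert "OUT_OF_RANGE" in body

    def test_multi_feature_body_is_atomic(self, service, store):
        """One bad feature voids the whole request: no partial writes."""
        body = doc_with(feat("good", 1, 5), feat("bad", 9, 12)).replace(
            "<START>9</START>", "<START>90</START>")  # bad: start 90 > end 12
        status, _ = post(service, body)
        assert status == 400
        assert store.record_count() == 0
        # same id twice in one create body is a conflict, also atomic
        status, _ = post(service, doc_with(feat("dup"), feat("dup")))
        assert status == 400
        assert store.record_count() == 0

    def test_no_write_on_any_error_response(self, service, store):
        """Across an error-heavy request mix, records appear only on 200."""
        requests = [
            WritebackRequest("POST", body=doc_with(feat()), credentials=ALICE),
            WritebackRequest("POST", body=doc_with(feat()), credentials=ALICE),
            WritebackRequest("PUT", body=doc_with(feat("nope")),
                             credentials=ALICE),
            WritebackRequest("DELETE", query={"segment": SEG, "feature": "f1"},
                             credentials=("alice", "bad")),
            WritebackRequest("DELETE", query={"segment": SEG, "feature": "f1"},
                             credentials=ALICE),
        ]
        counts = []
        for req in requests:
            before = store.record_count()
            status, _ = service.dispatch_request(req)
            after = store.record_count()
            counts.append((status, after - before))
        assert counts == [(200, 1), (400, 0), (404, 0), (401, 0), (200, 1)]


class TestDispatchTable:
    def test_method_query_pairs_map_to_exactly_one_operation(self, service,
                                                             store):
        """Every supported (method, query-shape) pair resolves to one store
        operation; unsupported methods are 405, never a write."""
        post(service, doc_with(feat()))  # seed one live feature
        shapes = {
            ("GET", "segment"): 200,
            ("GET", "segment+feature+history"): 200,
            ("POST", "body"): 400,        # f1 already live -> conflict
            ("PUT", "body"): 200,         # update
            ("PUT", "segment+feature+rollback"): 200,
            ("DELETE", "segment+feature"): 200,
        }
        for (method, shape), expected in shapes.items():
            query, body = {}, ""
            if "segment" in shape:
                query["segment"] = SEG
            if "feature" in shape:
                query["feature"] = "f1"
            if "history" in shape:
                query["history"] = "1"
            if "rollback" in shape:
                query["rollback"] = "1"
            if shape == "body":
                body = doc_with(feat(start=2, end=3))
            status, _ = service.dispatch_request(
                WritebackRequest(method, query=query, body=body,
                                 credentials=ALICE))
            assert status == expected, (method, shape)
        for method in ("HEAD", "OPTIONS", "PATCH", "TRACE"):
            status, _ = service.dispatch_request(
                WritebackRequest(method, credentials=ALICE))
            assert status == 405
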