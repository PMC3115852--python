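"""Version store semantics: append-only chains, tombstones, resurrection,
rollback fidelity, and agreement with a naive full-scan oracle."""

import threading

import pytest

from daswriteback import (Action, AnnotationStore, Feature, MemoryBackend,
                          SqliteBackend)
from daswriteback.errors import (ConflictError, InvalidTargetError,
                                 NotFoundError)
from daswriteback.fixtures import generate_edit_script, replay_script

SEG = "P12345"


def f(fid="f1", start=10, end=20, **kw):
    return Feature(feature_id=fid, type_id="domain", start=start, end=end,
                   **kw)


# ---------------------------------------------------------------------------
# oracle: resolve states by brute-force scan over all records


def oracle_states(store, segment_id, include_deleted):
    latest = {}
    for rec in store.backend.records():
        if rec.segment_id != segment_id:
            continue
        cur = latest.get(rec.feature_id)
        if cur is None or rec.version_number > cur.version_number:
            latest[rec.feature_id] = rec
    out = {}
    for fid, rec in latest.items():
        deleted = rec.action == Action.DELETE
        if deleted and not include_deleted:
            continue
        out[fid] = (rec.version_number, deleted, rec.payload)
    return out


def as_dict(states):
    return {s.feature_id: (s.latest_version, s.deleted, s.latest_payload)
            for s in states}


# ---------------------------------------------------------------------------


class TestLifecycle:
    def test_first_create_is_version_one(self, store):
        rec = store.create_feature(SEG, f(), "alice")
        assert (rec.version_number, rec.action) == (1, Action.CREATE)
        assert rec.user_id == "alice"

    def test_create_of_live_feature_conflicts(self, store):
        store.create_feature(SEG, f(), "alice")
        with pytest.raises(ConflictError):
            store.create_feature(SEG, f(), "bob")

    def test_update_returns_new_payload(self, store):
        store.create_feature(SEG, f(), "alice")
        rec = store.update_feature(SEG, "f1", f(start=5, end=8), "bob")
        assert (rec.version_number, rec.action) == (2, Action.UPDATE)
        (state,) = store.latest_state(SEG)
        assert (state.latest_payload.start, state.latest_payload.end) == (5, 8)
        assert state.last_user == "bob"

    def test_update_unknown_feature_not_found(self, store):
        with pytest.raises(NotFoundError):
            store.update_feature(SEG, "ghost", f("ghost"), "alice")

    def test_delete_sets_tombstone_with_snapshot(self, store):
        store.create_feature(SEG, f(), "alice")
        rec = store.delete_feature(SEG, "f1", "bob")
        assert rec.action is Action.DELETE
        assert rec.payload == f()  # snapshot of prior version
        (state,) = store.latest_state(SEG, include_deleted=True)
        assert state.deleted and state.latest_version == 2
        assert store.latest_state(SEG) == []
        assert [s.feature_id for s in store.deleted_features(SEG)] == ["f1"]

    def test_double_delete_conflicts(self, store):
        store.create_feature(SEG, f(), "alice")
        store.delete_feature(SEG, "f1", "alice")
        with pytest.raises(ConflictError):
            store.delete_feature(SEG, "f1", "alice")

    def test_update_of_deleted_feature_conflicts(self, store):
        store.create_feature(SEG, f(), "alice")
        store.delete_feature(SEG, "f1", "alice")
        with pytest.raises(ConflictError):
            store.update_feature(SEG, "f1", f(), "alice")

    def test_resurrection_continues_the_chain(self, store):
        store.create_feature(SEG, f(), "alice")       # v1
        store.update_feature(SEG, "f1", f(), "alice")  # v2
        store.delete_feature(SEG, "f1", "alice")       # v3
        rec = store.create_feature(SEG, f(start=1, end=3), "bob")
        assert (rec.version_number, rec.action) == (4, Action.CREATE)
        assert store.deleted_features(SEG) == []

    def test_history_actions_in_order(self, store):
        store.create_feature(SEG, f(), "alice")
        store.update_feature(SEG, "f1", f(start=2, end=4), "alice")
        store.delete_feature(SEG, "f1", "alice")
        hist = store.feature_history(SEG, "f1")
        assert [r.action for r in hist] == [Action.CREATE, Action.UPDATE,
                                            Action.DELETE]
        assert [r.version_number for r in hist] == [1, 2, 3]

    def test_history_of_unknown_feature_not_found(self, store):
        with pytest.raises(NotFoundError):
            store.feature_history(SEG, "ghost")

    def test_consecutive_updates_grow_history(self, store):
        store.create_feature(SEG, f(), "alice")
        for k in range(5):
            store.update_feature(SEG, "f1", f(start=k + 1, end=k + 2), "alice")
        assert len(store.feature_history(SEG, "f1")) == 6


class TestRollback:
    def setup_chain(self, store):
        store.create_feature(SEG, f(start=1, end=2), "alice")        # v1
        store.update_feature(SEG, "f1", f(start=3, end=4), "alice")  # v2
        store.update_feature(SEG, "f1", f(start=5, end=6), "alice")  # v3
        store.update_feature(SEG, "f1", f(start=7, end=8), "alice")  # v4

    def test_rollback_copies_target_payload(self, store):
        self.setup_chain(store)
        rec = store.rollback_feature(SEG, "f1", 2, "bob")
        assert (rec.version_number, rec.action) == (5, Action.UPDATE)
        assert rec.payload == f(start=3, end=4)
        hist = store.feature_history(SEG, "f1")
        assert [r.version_number for r in hist] == [1, 2, 3, 4, 5]

    def test_rollback_to_missing_version_not_found(self, store):
        self.setup_chain(store)
        with pytest.raises(NotFoundError):
            store.rollback_feature(SEG, "f1", 9, "bob")

    def test_rollback_to_delete_record_is_invalid(self, store):
        store.create_feature(SEG, f(), "alice")
        store.delete_feature(SEG, "f1", "alice")
        store.create_feature(SEG, f(), "alice")
        with pytest.raises(InvalidTargetError):
            store.rollback_feature(SEG, "f1", 2, "bob")


class TestStateResolution:
    def test_empty_store_empty_everything(self, store):
        assert store.latest_state(SEG) == []
        assert store.latest_state("UNKNOWN", include_deleted=True) == []
        assert store.deleted_features(SEG) == []

    def test_three_creates_one_delete(self, store):
        for i in range(3):
            store.create_feature(SEG, f(f"f{i}"), "alice")
        store.delete_feature(SEG, "f1", "alice")
        assert len(store.latest_state(SEG)) == 2
        assert len(store.latest_state(SEG, include_deleted=True)) == 3

    def test_segments_are_independent(self, store):
        store.create_feature("P1", f(), "alice")
        store.create_feature("P2", f(), "alice")  # same id, other segment
        assert len(store.latest_state("P1")) == 1
        assert len(store.latest_state("P2")) == 1


class TestScriptedProperties:
    """Randomized edit sessions checked against the full-scan oracle."""

    @pytest.mark.parametrize("seed", range(30))
    def test_latest_state_matches_oracle(self, seed):
        store = AnnotationStore()
        replay_script(generate_edit_script(seed, n_steps=25), store)
        for include_deleted in (False, True):
            assert as_dict(store.latest_state(SEG, include_deleted)) == \
                oracle_states(store, SEG, include_deleted)

    @pytest.mark.parametrize("seed", range(10))
    def test_chains_contiguous_and_append_only(self, seed):
        store = AnnotationStore()
        script = generate_edit_script(seed, n_steps=25)
        count = 0
        for i in range(len(script.steps)):
            partial = type(script)(seed=script.seed,
                                   segment_id=script.segment_id,
                                   sequence_length=script.sequence_length,
                                   steps=script.steps[: i + 1])
            s = AnnotationStore()
            replay_script(partial, s)
            assert s.record_count() == i + 1  # one append per step
            count = max(count, s.record_count())
        chains = {}
        replay_script(script, store)
        for rec in store.backend.records():
            chains.setdefault(rec.feature_id, []).append(rec.version_number)
        for versions in chains.values():
            assert sorted(versions) == list(range(1, len(versions) + 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_deleted_features_match_oracle(self, seed):
        store = AnnotationStore()
        replay_script(generate_edit_script(seed, n_steps=25), store)
        expected = {fid for fid, (v, deleted, p)
                    in oracle_states(store, SEG, True).items() if deleted}
        assert {s.feature_id for s in store.deleted_features(SEG)} == expected

    def test_every_record_attributed(self):
        store = AnnotationStore()
        replay_script(generate_edit_script(11, n_steps=40, n_users=4), store)
        assert all(r.user_id.startswith("user")
                   for r in store.backend.records())


class TestBackends:
    def test_sqlite_backend_round_trips_records(self, tmp_path, feature):
        path = str(tmp_path / "wb.sqlite")
        store = AnnotationStore(SqliteBackend(path))
        store.create_feature(SEG, feature, "alice")
        store.update_feature(SEG, feature.feature_id,
                             f(feature.feature_id, 1, 2), "bob")
        # reopen from disk
        store2 = AnnotationStore(SqliteBackend(path))
        hist = store2.feature_history(SEG, feature.feature_id)
        assert [r.version_number for r in hist] == [1, 2]
        assert hist[0].payload == feature
        assert hist[1].user_id == "bob"

    def test_sqlite_matches_memory_on_a_script(self, tmp_path):
        script = generate_edit_script(5, n_steps=30)
        mem = AnnotationStore(MemoryBackend())
        sql = AnnotationStore(SqliteBackend(str(tmp_path / "wb.sqlite")))
        replay_script(script, mem)
        replay_script(script, sql)
        assert {fid: (v, d) for fid, (v, d, p)
                in oracle_states(mem, SEG, True).items()} == \
            {fid: (v, d) for fid, (v, d, p)
             in oracle_states(sql, SEG, True).items()}


class TestConcurrency:
    def test_interleaved_writers_never_collide(self, store):
        """Simulated concurrent users produce contiguous chains and keep
        full attribution."""
        n_users, per_user = 8, 25
        errors = []

        def worker(uid):
            user = f"user{uid}"
            try:
                store.create_feature(SEG, f(f"feat-{uid}"), user)
                for k in range(per_user - 1):
                    store.update_feature(SEG, f"feat-{uid}",
                                         f(f"feat-{uid}", k + 1, k + 2), user)
            except Exception as exc:  # pragma: no cover
                errors.append(exc)

        threads = [threading.Thread(target=worker, args=(i,))
                   for i in range(n_users)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        assert not errors
        assert store.record_count() == n_users * per_user
        for uid in range(n_users):
            hist = store.feature_history(SEG, f"feat-{uid}")
            assert [r.version_number for r in hist] == \
                list(range(1, per_user + 1))
            assert {r.user_id for r in hist} == {f"user{uid}"}


class TestExportImport:
    def test_log_round_trips_through_dasgff(self, store, feature):
        store.create_feature(SEG, feature, "alice")
        store.update_feature(SEG, feature.feature_id,
                             f(feature.feature_id, 2, 3), "bob")
        store.delete_feature(SEG, feature.feature_id, "alice")
        docs = list(store.export_log({SEG: 100}))
        assert len(docs) == 3
        restored = AnnotationStore()
        assert restored.import_log(docs) == 3
        orig = store.feature_history(SEG, feature.feature_id)
        back = restored.feature_history(SEG, feature.feature_id)
        assert [(r.version_number, r.action, r.user_id, r.payload)
                for r in orig] == \
            [(r.version_number, r.action, r.user_id, r.payload)
             for r in back]
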