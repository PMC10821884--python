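"""Traceability semantics: lineage, override priority, diffs, save closure."""

import pytest
from hypothesis import given, settings, strategies as st

from fluxvault import (
    ConflictError,
    ConsistencyError,
    FormatError,
    LineageError,
    MissingReferenceError,
    ModificationEntry,
    ModificationFile,
    diff_modification_files,
    generate_lineage_fixture,
    parse_modification_file,
    resolve_effective_state,
    resolve_lineage,
    save_modification_file,
    serialize_modification_file,
)

K = lambda t: ModificationEntry(t, "knockout")
B = lambda t, lo, hi: ModificationEntry(t, "set_bounds", (lo, hi))


def _file(name, entries, parent=None, root="toy3", date="2024-01-01T00:00:00Z"):
    return ModificationFile(name, "alice", date, root, parent, tuple(entries))


def _persist(store, mod):
    store.add_modification_bytes(mod.root_model, mod.file_name,
                                 serialize_modification_file(mod))
    return mod


# -- parsing ----------------------------------------------------------------


class TestParsing:
    def test_minimal_file_no_parent(self):
        raw = (b"author: alice\ndate: 2024-01-01T00:00:00Z\nroot_model: toy3\n"
               b"modifications:\n- {target: R1, operation: knockout}\n")
        mod = parse_modification_file(raw, "m")
        assert mod.parent is None
        assert mod.entries == (K("R1"),)

    def test_parent_field_captured(self):
        raw = (b"author: a\ndate: d\nroot_model: toy3\nparent: modA\n"
               b"modifications: []\n")
        assert parse_modification_file(raw, "m").parent == "modA"

    @pytest.mark.parametrize("missing", ["author", "date", "root_model", "modifications"])
    def test_missing_mandatory_field(self, missing):
        fields = {"author": "a", "date": "d", "root_model": "toy3",
                  "modifications": "[]"}
        del fields[missing]
        raw = "\n".join(f"{k}: {v}" for k, v in fields.items()).encode()
        with pytest.raises(FormatError):
            parse_modification_file(raw, "m")

    def test_unknown_operation_rejected(self):
        raw = (b"author: a\ndate: d\nroot_model: toy3\n"
               b"modifications:\n- {target: R1, operation: overexpress}\n")
        with pytest.raises(FormatError):
            parse_modification_file(raw, "m")

    def test_set_bounds_inverted_payload_rejected(self):
        with pytest.raises(FormatError):
            ModificationEntry("R1", "set_bounds", (5.0, 0.0))

    def test_round_trip_identity(self):
        mod = _file("m", [K("R1"), B("R2", 0, 5)], parent="p")
        again = parse_modification_file(serialize_modification_file(mod), "m")
        assert again == mod

    def test_serialization_byte_stable(self):
        mod = _file("m", [K("R1"), B("R2", 0, 5)])
        raw = serialize_modification_file(mod)
        assert serialize_modification_file(parse_modification_file(raw, "m")) == raw


# -- lineage ----------------------------------------------------------------


class TestLineage:
    def test_parent_entries_first(self, store):
        p = _persist(store_with_root(store), _file("P", [K("R1")]))
        c = _file("C", [K("R2")], parent="P")
        assert resolve_lineage(c, store) == (K("R1"), K("R2"))

    def test_grandparent_chain_unrolls_ancestors_first(self, store):
        s = store_with_root(store)
        _persist(s, _file("G", [K("R1")]))
        _persist(s, _file("P", [K("R2")], parent="G"))
        c = _file("C", [K("R3")], parent="P")
        assert resolve_lineage(c, s) == (K("R1"), K("R2"), K("R3"))

    def test_self_parent_is_lineage_error(self, store):
        s = store_with_root(store)
        _persist(s, _file("C", [K("R1")], parent="C"))
        c = parse_modification_file(s.get_modification_bytes("C"), "C")
        with pytest.raises(LineageError):
            resolve_lineage(c, s)

    def test_two_cycle_detected(self, store):
        s = store_with_root(store)
        _persist(s, _file("X", [K("R1")], parent="Y"))
        _persist(s, _file("Y", [K("R2")], parent="X"))
        x = parse_modification_file(s.get_modification_bytes("X"), "X")
        with pytest.raises(LineageError):
            resolve_lineage(x, s)

    def test_missing_parent_is_reference_error(self, store):
        c = _file("C", [K("R1")], parent="nowhere")
        with pytest.raises(MissingReferenceError):
            resolve_lineage(c, store_with_root(store))

    def test_duplicate_entries_collapsed(self, store):
        s = store_with_root(store)
        _persist(s, _file("P", [K("R1"), K("R1")]))
        c = _file("C", [K("R1"), K("R2")], parent="P")
        assert resolve_lineage(c, s) == (K("R1"), K("R2"))

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("depth", [1, 3, 5])
    def test_lineage_equals_concatenation_oracle(self, store, seed, depth):
        """Brute-force oracle: expansion == explicit ancestor-list concatenation."""
        files = generate_lineage_fixture(depth, 2, seed, store=store)
        child = files[-1]
        expected = tuple(e for f in files for e in f.entries)
        assert resolve_lineage(child, store) == expected
        assert len(expected) == depth * 2  # targets drawn without replacement

    def test_depth_one_file_has_no_parent(self, store):
        (single,) = generate_lineage_fixture(1, 2, 7, store=store)
        assert single.parent is None

    def test_lineage_fixture_deterministic(self, tmp_path):
        from fluxvault import ModelStore

        a = generate_lineage_fixture(3, 2, 11, store=ModelStore(tmp_path / "a"))
        b = generate_lineage_fixture(3, 2, 11, store=ModelStore(tmp_path / "b"))
        assert a == b


def store_with_root(store):
    from fluxvault import FixtureSpec, generate_toy_model

    if not store.list_models():
        sbml, _ = generate_toy_model(FixtureSpec("chain", 6, 0))
        store.register_model(sbml, "toy3")
    return store


# -- override resolution ----------------------------------------------------


class TestEffectiveState:
    def test_last_loaded_wins(self, store):
        s = store_with_root(store)
        f1 = _persist(s, _file("F1", [B("R1", 0, 5)]))
        f2 = _persist(s, _file("F2", [K("R1")]))
        state = resolve_effective_state([f1, f2], s)
        win = state.winner("R1")
        assert win.entry == K("R1") and win.file_name == "F2"

    def test_order_reversal_flips_winner(self, store):
        s = store_with_root(store)
        f1 = _persist(s, _file("F1", [B("R1", 0, 5)]))
        f2 = _persist(s, _file("F2", [K("R1")]))
        state = resolve_effective_state([f2, f1], s)
        assert state.winner("R1").entry == B("R1", 0, 5)

    def test_disjoint_targets_one_winner_each(self, store):
        s = store_with_root(store)
        f1 = _persist(s, _file("F1", [K("R1")]))
        f2 = _persist(s, _file("F2", [K("R2")]))
        state = resolve_effective_state([f1, f2], s)
        assert state.targets == {"R1", "R2"}

    def test_later_entry_wins_within_one_file(self, store):
        s = store_with_root(store)
        f = _persist(s, _file("F", [B("R1", 0, 5), K("R1")]))
        assert resolve_effective_state([f], s).winner("R1").entry == K("R1")

    def test_mixed_root_models_rejected(self, store):
        s = store_with_root(store)
        f1 = _file("F1", [K("R1")], root="toy3")
        f2 = _file("F2", [K("R2")], root="other")
        with pytest.raises(ConsistencyError):
            resolve_effective_state([f1, f2], s)

    def test_reorder_flips_exactly_the_conflicting_targets(self, store):
        """Loading [F1,F2] vs [F2,F1] changes winners only where targets clash."""
        s = store_with_root(store)
        f1 = _persist(s, _file("F1", [B("R1", 0, 5), K("R2")]))
        f2 = _persist(s, _file("F2", [K("R1"), B("R3", 1, 2)]))
        fwd = resolve_effective_state([f1, f2], s).as_mapping()
        rev = resolve_effective_state([f2, f1], s).as_mapping()
        assert set(fwd) == set(rev) == {"R1", "R2", "R3"}
        changed = {t for t in fwd if fwd[t] != rev[t]}
        assert changed == {"R1"}  # only the shared target


# -- diff -------------------------------------------------------------------


class TestDiff:
    def test_partition(self, store):
        s = store_with_root(store)
        a = _file("A", [K("R1"), K("R2")])
        b = _file("B", [K("R2"), B("R3", 0, 1)])
        only_a, common, only_b = diff_modification_files(a, b, s)
        assert only_a == [K("R1")]
        assert common == [K("R2")]
        assert only_b == [B("R3", 0, 1)]

    def test_self_diff_all_common(self, store):
        s = store_with_root(store)
        a = _file("A", [K("R1"), B("R2", 0, 2)])
        only_a, common, only_b = diff_modification_files(a, a, s)
        assert only_a == [] and only_b == []
        assert common == list(a.entries)

    def test_child_vs_parent_isolates_own_entries(self, store):
        s = store_with_root(store)
        p = _persist(s, _file("P", [K("R1")]))
        c = _file("C", [K("R2")], parent="P")
        only_c, common, only_p = diff_modification_files(c, p, s)
        assert only_c == [K("R2")]
        assert common == [K("R1")]
        assert only_p == []

    def test_partition_sizes_exhaustive(self, store):
        s = store_with_root(store)
        a = _file("A", [K("R1"), K("R2"), B("R3", 0, 1)])
        b = _file("B", [K("R2")])
        only_a, common, only_b = diff_modification_files(a, b, s)
        assert len(only_a) + len(common) == len(resolve_lineage(a, s))
        assert len(only_b) + len(common) == len(resolve_lineage(b, s))


# -- save -------------------------------------------------------------------


class TestSave:
    def test_carries_unshared_entries_from_earlier_files(self, store):
        s = store_with_root(store)
        f1 = _persist(s, _file("F1", [K("R1")]))
        f2 = _persist(s, _file("F2", [K("R2")]))
        saved = save_modification_file([f1, f2], [B("R3", 0, 1)], "bob", s, "S")
        assert saved.parent == "F2"
        # R2 lives in the parent and is not duplicated; R1 is new wrt parent
        assert saved.entries == (K("R1"), B("R3", 0, 1))

    def test_no_lineage_no_parent(self, store):
        s = store_with_root(store)
        saved = save_modification_file([], [K("R1")], "bob", s, "S", root_model="toy3")
        assert saved.parent is None and saved.entries == (K("R1"),)

    def test_empty_session_is_pure_checkpoint(self, store):
        s = store_with_root(store)
        f2 = _persist(s, _file("F2", [K("R2")]))
        saved = save_modification_file([f2], [], "bob", s, "S")
        assert saved.parent == "F2" and saved.entries == ()

    def test_name_collision_conflicts(self, store):
        s = store_with_root(store)
        save_modification_file([], [K("R1")], "bob", s, "S", root_model="toy3")
        with pytest.raises(ConflictError):
            save_modification_file([], [K("R2")], "bob", s, "S", root_model="toy3")

    def test_saved_file_is_listed(self, store):
        s = store_with_root(store)
        save_modification_file([], [K("R1")], "bob", s, "S", root_model="toy3")
        assert "S" in s.list_modification_files("toy3")

    @pytest.mark.parametrize("seed", range(8))
    def test_save_load_closure(self, store, seed):
        """Loading only the saved file reproduces the whole session state."""
        s = store_with_root(store)
        files = generate_lineage_fixture(3, 2, seed, store=s, root_model="toy3")
        session = [B(files[0].entries[0].target, 0.0, 2.0)]
        saved = save_modification_file(files, session, "bob", s, f"S{seed}")
        original = resolve_effective_state(files, s)
        for e in session:
            original.record(e, f"S{seed}", len(files))
        replayed = resolve_effective_state([saved], s)
        assert replayed == original


# -- property: random load orders ------------------------------------------

entry_st = st.builds(
    lambda t, op, lo, span: ModificationEntry(
        f"R{t}", op, (lo, lo + span) if op == "set_bounds" else None
    ),
    st.integers(0, 4),
    st.sampled_from(["knockout", "set_bounds"]),
    st.integers(0, 3).map(float),
    st.integers(0, 5).map(float),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.lists(entry_st, max_size=4), min_size=1, max_size=4))
def test_override_winner_is_last_occurrence(file_entries):
    """For parentless files, the winner per target is simply the last entry
    targeting it across the concatenated load sequence (independent oracle)."""

    class NullStore:
        def get_modification_bytes(self, name):
            raise AssertionError("no parents involved")

    files = [_file(f"F{i}", entries) for i, entries in enumerate(file_entries)]
    state = resolve_effective_state(files, NullStore())
    flat = [e for entries in file_entries for e in entries]
    expected = {}
    for e in flat:
        expected[e.target] = e
    assert state.as_mapping() == expected
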