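import numpy as np
import pytest
import scipy.sparse as sp

import hicder as h
from hicder.genome_model import HicderError
from hicder.rearrange_engine import expected_from_rearranged
from conftest import make_matrix
from bruteforce_oracle import (
    oracle_delete,
    oracle_duplicate,
    oracle_identity,
    oracle_invert,
    oracle_materialize,
    random_symmetric_counts,
)


def identity_map(n, offset=0):
    return h.BinMap(
        np.arange(offset, offset + n),
        np.ones(n, dtype=np.int8),
        np.zeros(n, dtype=np.int64),
    )


class TestApplyEdit:
    def test_invert_flips_order_and_orientation(self):
        bm = h.apply_edit(identity_map(6), h.EditOp("invert", "d", 1, 5))
        assert bm.source_bins.tolist() == [0, 4, 3, 2, 1, 5]
        assert bm.orientations.tolist() == [1, -1, -1, -1, -1, 1]

    def test_invert_is_an_involution(self):
        bm = identity_map(8)
        e = h.EditOp("invert", "d", 2, 6)
        assert h.apply_edit(h.apply_edit(bm, e), e) == bm

    def test_delete_matches_list_editor(self, rng):
        bm = identity_map(10)
        got = h.apply_edit(bm, h.EditOp("delete", "d", 3, 7))
        assert got.source_bins.tolist() == [
            s for s, _ in oracle_delete(oracle_identity(10), 3, 7)
        ]

    def test_duplicate_is_tandem(self):
        got = h.apply_edit(identity_map(6), h.EditOp("duplicate", "d", 2, 4))
        assert got.source_bins.tolist() == [0, 1, 2, 3, 2, 3, 4, 5]

    def test_out_of_range_interval(self):
        with pytest.raises(HicderError):
            h.apply_edit(identity_map(6), h.EditOp("delete", "d", 2, 9))

    def test_fragment_runs_stay_contiguous(self):
        bm = h.apply_edit(identity_map(10), h.EditOp("invert", "d", 3, 6))
        fid = bm.fragment_ids
        # runs contiguous, + runs increase, - runs decrease
        for f in np.unique(fid):
            idx = np.where(fid == f)[0]
            assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
            step = np.diff(bm.source_bins[idx])
            assert np.all(step == bm.orientations[idx][1:])


class TestEditSequence:
    def test_empty_sequence_is_identity(self):
        state = {"d": identity_map(5)}
        session = h.apply_edit_sequence(state, [])
        assert session.state["d"] == state["d"]

    def test_deletion_then_inversion_matches_list_editor(self):
        """Sequential deletion + inversion on a toy 20-bin chromosome."""
        state = {"d": identity_map(20)}
        edits = [
            h.EditOp("delete", "d", 5, 10),
            h.EditOp("invert", "d", 2, 8),
        ]
        session = h.apply_edit_sequence(state, edits)
        ora = oracle_invert(oracle_delete(oracle_identity(20), 5, 10), 2, 8)
        assert session.state["d"].source_bins.tolist() == [s for s, _ in ora]
        assert session.state["d"].orientations.tolist() == [o for _, o in ora]

    def test_undo_stack_discipline(self, rng):
        state = {"d": identity_map(30)}
        session = h.EditSession(state)
        for kind, a, b in [("delete", 3, 6), ("invert", 1, 10), ("duplicate", 5, 9)]:
            session.apply(h.EditOp(kind, "d", a, b))
        for _ in range(3):
            session.undo()
        assert session.state["d"] == state["d"]
        with pytest.raises(HicderError):
            session.undo()

    def test_first_invalid_edit_reports_its_index(self):
        with pytest.raises(HicderError, match="edit 1"):
            h.apply_edit_sequence(
                {"d": identity_map(5)},
                [h.EditOp("delete", "d", 0, 2), h.EditOp("delete", "d", 0, 99)],
            )

    def test_join_consumes_second_derivative(self):
        state = {"a": identity_map(4), "b": identity_map(3, offset=4)}
        session = h.EditSession(state)
        session.apply(h.EditOp("join", "a", 2, 0, "3", "b", 1, "5"))
        assert set(session.state) == {"a"}
        assert session.state["a"].source_bins.tolist() == [0, 1, 5, 6]
        session.undo()
        assert set(session.state) == {"a", "b"}


class TestOrderSpec:
    def test_grammar_with_strands(self, bt_small):
        ders = h.parse_order_spec(
            "der1\tchrA:1-200000+;chrB:100001-150000-", bt_small
        )
        assert ders[0].fragments == (
            h.Fragment("chrA", 0, 200_000, "+"),
            h.Fragment("chrB", 100_000, 150_000, "-"),
        )

    def test_single_full_chromosome_is_identity(self, bt_small):
        (der,) = h.parse_order_spec("d\tchrA:1-400000", bt_small)
        bm = h.derivative_to_binmap(bt_small, der)
        assert bm == h.identity_binmap(bt_small, "chrA")

    def test_two_lines_two_derivatives(self, bt_small):
        ders = h.parse_order_spec(
            "d1\tchrA:1-400000\nd2\tchrB:1-150000", bt_small
        )
        assert [d.name for d in ders] == ["d1", "d2"]

    @pytest.mark.parametrize(
        "text, match",
        [
            ("d\tchrZ:1-100", "unknown chromosome"),
            ("d\tchrA:500-100", "invalid range"),
            ("d\tchrA:1:100", "chrom:start-end"),
            ("d\tchrA:1-9999999", "beyond"),
        ],
    )
    def test_syntax_errors_located(self, bt_small, text, match):
        with pytest.raises(HicderError, match=match):
            h.parse_order_spec(text, bt_small)

    def test_round_trip(self, bt_small):
        text = "der1\tchrA:1-200000+;chrB:100001-150000-\nder2\tchrB:1-150000+\n"
        ders = h.parse_order_spec(text, bt_small)
        assert h.parse_order_spec(h.serialize_order_spec(ders), bt_small) == ders


class TestEditScript:
    def test_parse_and_round_trip(self):
        text = "DEL der1:12-40\nINV der1:5-9\nDUP der1:20-24\nJOIN der1:15/3 der2:0/5\n"
        edits = h.parse_edit_script(text)
        assert [e.kind for e in edits] == ["delete", "invert", "duplicate", "join"]
        assert (edits[0].start, edits[0].stop) == (11, 40)  # 1-based inclusive
        assert h.parse_edit_script(h.serialize_edit_script(edits)) == edits

    def test_bad_lines(self):
        for text in ["FLIP d:1-2", "DEL d:9-2", "JOIN d:1/9 e:0/5"]:
            with pytest.raises(HicderError):
                h.parse_edit_script(text)


class TestMaterialize:
    def test_identity_is_bit_exact(self, cm_small):
        bms = {
            c: h.identity_binmap(cm_small.bintable, c)
            for c in cm_small.bintable.chrom_names
        }
        rm = h.materialize(cm_small, bms, w=1.0)
        np.testing.assert_array_equal(rm.values, cm_small.dense())

    def test_whole_chromosome_inversion_hand_example(self):
        bt = h.make_bintable([("chrA", 300_000)], 100_000)
        cm = make_matrix(bt, np.array([[10, 5, 1], [5, 8, 4], [1, 4, 9]]))
        bm = h.apply_edit(identity_map(3), h.EditOp("invert", "d", 0, 3))
        rm = h.materialize(cm, bm)
        np.testing.assert_array_equal(
            rm.values, [[9, 4, 1], [4, 8, 5], [1, 5, 10]]
        )

    def test_weight_scales_trans_sources_only(self, bt_small):
        dense = np.zeros((6, 6))
        dense[0, 1] = dense[1, 0] = 5  # cis (chrA)
        dense[0, 4] = dense[4, 0] = 2  # trans (chrA-chrB)
        cm = make_matrix(bt_small, dense)
        bms = {c: h.identity_binmap(bt_small, c) for c in bt_small.chrom_names}
        rm1 = h.materialize(cm, bms, w=1.0)
        rm3 = h.materialize(cm, bms, w=3.0)
        assert rm3.values[0, 4] == 6 and rm1.values[0, 4] == 2
        assert rm3.values[0, 1] == 5  # intra-chromosomal untouched
        np.testing.assert_array_equal(
            (rm3.values - rm1.values)[np.ix_([0, 1, 2, 3], [0, 1, 2, 3])], 0
        )

    def test_duplication_replicates_source_blocks(self):
        bt = h.make_bintable([("chrA", 500_000)], 100_000)
        dense = random_symmetric_counts(np.random.default_rng(3), 5)
        cm = make_matrix(bt, dense)
        bm = h.apply_edit(identity_map(5), h.EditOp("duplicate", "d", 1, 3))
        rm = h.materialize(cm, bm)
        # dup-dup block equals the source self-block
        np.testing.assert_array_equal(rm.values[3:5, 3:5], dense[1:3, 1:3])
        np.testing.assert_array_equal(rm.values[1:3, 3:5], dense[1:3, 1:3])

    def test_permutation_preserves_value_multiset(self, cm_small, rng):
        n = cm_small.n_bins
        perm = rng.permutation(n)
        bm = h.BinMap(perm, np.ones(n, dtype=np.int8), np.arange(n))
        rm = h.materialize(cm_small, bm)
        assert sorted(rm.values[np.triu_indices(n)].tolist()) == sorted(
            np.asarray(cm_small.dense(), dtype=float)[np.triu_indices(n)].tolist()
        )

    def test_symmetry_preserved(self, cm_small, rng):
        bm = h.apply_edit(
            identity_map(cm_small.n_bins), h.EditOp("invert", "d", 1, 5)
        )
        rm = h.materialize(cm_small, bm, w=2.0)
        np.testing.assert_array_equal(rm.values, rm.values.T)

    def test_whole_derivative_reversal_reverses_both_axes(self, cm_small):
        bm = h.apply_edit(
            identity_map(cm_small.n_bins), h.EditOp("delete", "d", 2, 4)
        )
        rev = h.BinMap(
            bm.source_bins[::-1], -bm.orientations[::-1], bm.fragment_ids[::-1]
        )
        a = h.materialize(cm_small, bm).values
        b = h.materialize(cm_small, rev).values
        np.testing.assert_array_equal(b, a[::-1, ::-1])


class TestOracleEquivalence:
    def test_randomized_edit_trials_match_bruteforce(self):
        """materialize(apply_edit_sequence(...)) equals explicit per-bin list
        editing, exactly, over 100 randomized trials (<=5 edits, 100-300 bins,
        1-3 chromosomes)."""
        rng = np.random.default_rng(777)
        r = 100_000
        for _ in range(100):
            n_chrom = int(rng.integers(1, 4))
            sizes = []
            total = int(rng.integers(100, 301))
            cuts = sorted(rng.choice(np.arange(1, total), n_chrom - 1, replace=False).tolist())
            edges = [0] + cuts + [total]
            for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
                sizes.append((f"chr{k}", (b - a) * r))
            bt = h.make_bintable(sizes, r)
            dense = random_symmetric_counts(rng, total, max_count=9)
            cm = make_matrix(bt, dense)

            lst = oracle_identity(total)
            bm = identity_map(total)
            n_edits = int(rng.integers(0, 6))
            for _ in range(n_edits):
                ln = len(lst)
                if ln < 4:
                    break
                a = int(rng.integers(0, ln - 1))
                b = int(rng.integers(a + 1, min(ln, a + 40) + 1))
                kind = rng.choice(["delete", "invert", "duplicate"])
                if kind == "delete" and b - a >= ln:
                    continue
                lst = {
                    "delete": oracle_delete,
                    "invert": oracle_invert,
                    "duplicate": oracle_duplicate,
                }[kind](lst, a, b)
                bm = h.apply_edit(bm, h.EditOp(str(kind), "d", a, b))
            assert bm.source_bins.tolist() == [s for s, _ in lst]
            rm = h.materialize(cm, bm)
            expected = oracle_materialize(dense, lst)
            np.testing.assert_array_equal(rm.values, expected)


class TestJunctionSmoothness:
    def _sim_deleted(self, seed=7):
        p = h.SimParams(
            chrom_sizes=[("chr1", 10_000_000)],
            binsize=40_000,
            seed=seed,
            alpha=1.0,
            beta=1.0,
            trans_level=0.0,
        )
        sv = h.parse_sv_table("chr1 3000001 chr1 6000001 DEL 3to5")[0]
        return h.simulate_rearranged(p, [sv]), sv

    def test_contiguous_map_scores_near_one(self):
        p = h.SimParams(
            chrom_sizes=[("chr1", 8_000_000)],
            binsize=40_000,
            seed=11,
            alpha=1.0,
            beta=1.0,
            trans_level=0.0,
        )
        cm, _ = h.simulate_reference(p)
        rm = h.materialize(cm, h.identity_binmap(cm.bintable, "chr1"))
        profile = expected_from_rearranged(rm)
        rep = h.junction_smoothness(rm, profile, 100, 10)
        assert 0.8 <= rep.score <= 1.25

    def test_true_junction_scores_one_and_gap_scores_low(self):
        (cm, truth), sv = self._sim_deleted()
        der = truth.derivatives[0]
        rm = h.materialize(cm, truth.binmaps[der.name])
        profile = expected_from_rearranged(rm)
        rep = h.junction_smoothness(rm, profile, rm.junctions[0], 10)
        assert 0.8 <= rep.score <= 1.25
        # same reference gap, no rearrangement: right window is the deleted
        # region, observed/expected collapses
        rm_id = h.materialize(cm, h.identity_binmap(cm.bintable, "chr1"))
        cut = h.pos_to_bin(cm.bintable, "chr1", sv.pos1) + 1
        rep_id = h.junction_smoothness(
            rm_id, expected_from_rearranged(rm_id), cut, 10
        )
        assert rep_id.score < 0.8

    def test_all_zero_window_scores_zero_with_n_recorded(self, bt_small):
        cm = h.ContactMatrix(bt_small, sp.coo_matrix((6, 6)))
        rm = h.materialize(cm, identity_map(6))
        profile = h.ExpectedProfile(pooled=np.ones(6), scope="pooled")
        rep = h.junction_smoothness(rm, profile, 3, 2)
        assert rep.score == 0.0 and rep.n_pairs == 4

    def test_errors(self, cm_small):
        rm = h.materialize(cm_small, identity_map(6))
        profile = h.ExpectedProfile(pooled=np.ones(6), scope="pooled")
        with pytest.raises(HicderError):
            h.junction_smoothness(rm, profile, 3, 0)  # k = 0
        with pytest.raises(HicderError):
            h.junction_smoothness(rm, profile, 6, 2)  # at axis end
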