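"""Position-shift maps, block partitioning and separation metrics."""

import numpy as np
import pytest

from alignerr.errors import DomainError
from alignerr.inject import find_targets, inject_elementary_error
from alignerr.msa import Msa, canonicalize, homology_structure
from alignerr.phylo import tree_from_newick
from alignerr.segments import partition_into_segments
from alignerr.shiftmap import (
    SeparationMetrics,
    build_position_shift_map,
    partition_shift_blocks,
    realign_by_shifts,
    separation_metrics,
)


def _series_and_segment(true_rows, rec_rows, names=("s1", "s2")):
    t = canonicalize(Msa(names, true_rows))
    r = canonicalize(Msa(names, rec_rows))
    series = partition_into_segments(t, r)
    errs = series.erroneous()
    assert len(errs) == 1
    return series, errs[0]


class TestBuildPositionShiftMap:
    def test_worked_example(self):
        # one gap moved one column right in s1; s2 untouched
        series, seg = _series_and_segment(
            ("AA-CG", "AAGCG"), ("AAC-G", "AAGCG"))
        smap = build_position_shift_map(series, seg)
        by_name = dict(zip(smap.names, smap.shifts))
        # drawn on the reconstruction: s1's C moved left by one (shift -1)
        s1 = [s for s in by_name["s1"] if s is not None]
        s2 = [s for s in by_name["s2"] if s is not None]
        assert s1 == [-1]
        assert all(s == 0 for s in s2)

    def test_correct_segment_rejected(self):
        t = canonicalize(Msa(("a", "b"), ("ACGT", "ACGT")))
        series = partition_into_segments(t, t)
        with pytest.raises(DomainError):
            build_position_shift_map(series, series.segments[0])

    def test_target_choice_preserves_values(self, tree8, sim8_pool):
        """Both canvases show the same multiset of residue shifts."""
        res = sim8_pool[0]
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "shift")[0]).rec
        series = partition_into_segments(res.msa, rec)
        seg = series.erroneous()[0]
        on_rec = build_position_shift_map(series, seg, target="reconstructed")
        on_true = build_position_shift_map(series, seg, target="true")
        vals_rec = sorted(s for row in on_rec.shifts for s in row if s is not None)
        vals_true = sorted(s for row in on_true.shifts for s in row if s is not None)
        assert vals_rec == vals_true

    def test_antisymmetry_under_role_swap(self, tree8, sim8_pool):
        """Swapping which alignment plays 'true' negates every shift."""
        res = sim8_pool[0]
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "shift")[0]).rec
        fwd = partition_into_segments(res.msa, rec)
        back = partition_into_segments(rec, res.msa)
        m_fwd = build_position_shift_map(fwd, fwd.erroneous()[0])
        m_back = build_position_shift_map(back, back.erroneous()[0])
        v_fwd = sorted(s for row in m_fwd.shifts for s in row if s is not None)
        v_back = sorted(-s for row in m_back.shifts for s in row if s is not None)
        assert v_fwd == v_back

    def test_zero_iff_identical_subalignments(self, tree8, sim8_pool):
        res = sim8_pool[1]
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "shift")[0]).rec
        series = partition_into_segments(res.msa, rec)
        smap = build_position_shift_map(series, series.erroneous()[0])
        assert not smap.is_zero()


class TestPartitionShiftBlocks:
    def test_single_moved_gap_is_one_block(self, tree8, sim8_pool):
        res = sim8_pool[0]
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "shift")[0]).rec
        series = partition_into_segments(res.msa, rec)
        smap = build_position_shift_map(series, series.erroneous()[0])
        blocks = partition_shift_blocks(smap, tree8)
        assert len(blocks) == 1

    def test_intervening_leaf_with_other_shift_separates_runs(self, tree3):
        """3-leaf adjacency audit: same-shift runs in A and C stay separate
        when gap-free B carries a different shift in the overlap."""
        from alignerr.msa import AlnBlock
        from alignerr.shiftmap import ShiftMap

        smap = ShiftMap(
            target="reconstructed",
            names=("A", "B", "C"),
            shifts=((2, 2), (1, 1), (2, 2)),
            target_block=AlnBlock(("A", "B", "C"), ("AA", "AA", "AA")),
        )
        blocks = partition_shift_blocks(smap, tree3)
        shifts = sorted(b.shift for b in blocks)
        assert shifts == [1, 2, 2]  # A and C do not merge across B

    def test_gap_only_intervening_leaf_does_not_separate(self, tree3):
        from alignerr.msa import AlnBlock
        from alignerr.shiftmap import ShiftMap

        smap = ShiftMap(
            target="reconstructed",
            names=("A", "B", "C"),
            shifts=((2, 2), (None, None), (2, 2)),
            target_block=AlnBlock(("A", "B", "C"), ("AA", "--", "AA")),
        )
        blocks = partition_shift_blocks(smap, tree3)
        assert len(blocks) == 1 and blocks[0].rows == frozenset("AC")

    def test_invariant_to_sequence_reordering(self, tree8, sim8_pool):
        res = next(r for r in sim8_pool
                   if find_targets(r.msa, tree8, "split"))
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "split")[0]).rec
        order = np.random.default_rng(0).permutation(len(rec.names))
        rec_shuffled = Msa(
            tuple(rec.names[i] for i in order),
            tuple(rec.rows[i] for i in order),
        )
        base, shuffled = [], []
        for r in (rec, rec_shuffled):
            series = partition_into_segments(res.msa, r)
            smap = build_position_shift_map(series, series.erroneous()[0])
            blocks = partition_shift_blocks(smap, tree8)
            sig = sorted((b.shift, b.col_span, b.length, tuple(sorted(b.rows)))
                         for b in blocks)
            (base if r is rec else shuffled).append(sig)
        assert base == shuffled

    def test_block_moves_recover_true_homology(self, tree8, sim8_pool):
        """Undoing all block moves turns the reconstruction's segment into
        the true segment's homology structure."""
        for res in sim8_pool[:3]:
            for typ in ("shift", "split", "ex_nihilo"):
                targets = find_targets(res.msa, tree8, typ)
                if not targets:
                    continue
                rec = inject_elementary_error(res.msa, tree8, targets[0]).rec
                series = partition_into_segments(res.msa, rec)
                seg = series.erroneous()[0]
                smap = build_position_shift_map(series, seg)
                restored = realign_by_shifts(smap)
                tb = series.true_block(seg)
                assert homology_structure(restored).key == \
                    homology_structure(tb).key

    def test_weighted_moves_lower_bound(self, tree8, sim8_pool):
        """Any erroneous segment needs at least one site-wise move."""
        res = sim8_pool[0]
        rec = inject_elementary_error(
            res.msa, tree8, find_targets(res.msa, tree8, "shift")[0]).rec
        series = partition_into_segments(res.msa, rec)
        smap = build_position_shift_map(series, series.erroneous()[0])
        blocks = partition_shift_blocks(smap, tree8)
        assert sum(b.length * abs(b.shift) for b in blocks) >= 1


class TestSeparationMetrics:
    def test_empty_blocks(self):
        m = separation_metrics([])
        assert (m.n_blocks, m.total_path_length, m.max_block_length) == (0, 0, 0)
        assert not (m.many_blocks or m.many_sites or m.long_block)

    @pytest.mark.parametrize(
        "n_blocks,lengths,flags",
        [
            (5, [1] * 5, (True, False, False)),   # 5 block-wise steps
            (1, [30], (False, True, True)),        # 30 site-wise steps, long
            (4, [7, 7, 7, 8], (False, False, False)),
        ],
    )
    def test_threshold_boundaries(self, n_blocks, lengths, flags):
        from alignerr.shiftmap import ShiftBlock

        blocks = [
            ShiftBlock(shift=1, members=(), rows=frozenset({"A"}),
                       col_span=(0, L), length=L)
            for L in lengths
        ]
        m = separation_metrics(blocks)
        assert (m.many_blocks, m.many_sites, m.long_block) == flags
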