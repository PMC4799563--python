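"""Parsimonious indel histories: enumeration, weights, counts, measures."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alignerr.errors import DomainError, IntractableSegmentError
from alignerr.histories import (
    IndelCounts,
    enumerate_parsimonious_histories,
    expected_indel_counts,
    history_weight,
    misestimation_measures,
    weight_ensemble,
)
from alignerr.msa import AlnBlock, gap_segmentation
from alignerr.phylo import tree_from_newick
from alignerr.sim import IndelModel, ZipfIndelLength, simulate_true_msa

from tests._oracles import history_key, oracle_parsimonious_histories


def _keys(ens):
    return {history_key(h) for h in ens.histories}


class TestEnumeration:
    def test_gap_only_in_one_leaf_has_two_explanations(self, tree3):
        """Deletion on the leaf's branch or insertion on the sister stem."""
        blk = AlnBlock(("A", "B", "C"), ("AA", "AA", "--"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        assert len(ens.histories) == 2
        kinds = sorted(
            (h.events[0].kind, tree3.label[h.events[0].branch])
            for h in ens.histories
        )
        assert kinds == [("deletion", "C"), ("insertion", None)]

    def test_gap_in_sister_pair(self, tree3):
        """Deletion on the AB stem ties with an insertion on C's branch."""
        blk = AlnBlock(("A", "B", "C"), ("-", "-", "A"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        assert _keys(ens) == oracle_parsimonious_histories(blk, tree3)
        assert len(ens.histories) == 2

    def test_gapless_block_is_single_empty_history(self, tree3):
        blk = AlnBlock(("A", "B", "C"), ("ACG", "ACG", "ACG"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        assert len(ens.histories) == 1 and ens.histories[0].events == ()
        assert ens.weights == [1.0]

    def test_cross_run_merging_variant_found(self, tree3):
        """Runs absent{A,B} then absent{A}: a split cover of the first run
        lets one deletion span both runs, tying at two events."""
        blk = AlnBlock(("A", "B", "C"), ("---", "--G", "CCC"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        assert _keys(ens) == oracle_parsimonious_histories(blk, tree3)
        assert len(ens.histories) == 3

    def test_every_history_replays(self, tree8, sim8_pool):
        """Each enumerated history must reproduce its segment's pattern
        when checked by the oracle's independent replay."""
        from tests._oracles import _replays, block_patterns

        from alignerr.errors import IntractableSegmentError

        res = sim8_pool[0]
        seg = gap_segmentation(res.msa)
        checked = 0
        for a, b in seg.gapped_spans[:14]:
            blk = AlnBlock(res.msa.names, tuple(r[a:b] for r in res.msa.rows))
            try:
                ens = enumerate_parsimonious_histories(blk, tree8)
            except IntractableSegmentError:
                continue
            patterns = block_patterns(blk, tree8)
            for h in ens.histories:
                events = [(e.kind, e.branch, frozenset(e.runs)) for e in h.events]
                assert _replays(events, patterns, tree8)
                checked += 1
        assert checked >= 10

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_on_random_patterns(self, tree4, data):
        """Random <=4-leaf, <=4-run segments: the enumerated set equals the
        exhaustive search over all event sets of minimal size."""
        n_runs = data.draw(st.integers(1, 3))
        masks = [
            data.draw(st.integers(1, 14))  # never 0 (all-gap) nor 15 (gapless)
            for _ in range(n_runs)
        ]
        # merge equal adjacent masks into single runs
        rows = []
        for leaf in range(4):
            row = "".join(
                "A" if m >> leaf & 1 else "-" for m in masks
            )
            rows.append(row)
        blk = AlnBlock(("A", "B", "C", "D"), tuple(rows))
        ens = enumerate_parsimonious_histories(blk, tree4)
        assert _keys(ens) == oracle_parsimonious_histories(blk, tree4)

    def test_logged_true_history_lower_bound(self, tree8):
        """The minimal event count never exceeds the number of simulated
        events that touched the segment's columns."""
        res = simulate_true_msa(tree8, root_length=300, seed=77, canonical=False)
        all_events = [e for evs in res.events.values() for e in evs]
        seg = gap_segmentation(res.msa)
        for a, b in seg.gapped_spans[:8]:
            blk = AlnBlock(res.msa.names, tuple(r[a:b] for r in res.msa.rows))
            try:
                ens = enumerate_parsimonious_histories(blk, tree8)
            except (DomainError, IntractableSegmentError):
                continue
            assert min(h.n_events for h in ens.histories) <= len(all_events)


class TestWeights:
    def test_empty_history_weight_is_one(self, tree3):
        blk = AlnBlock(("A", "B", "C"), ("ACG", "ACG", "ACG"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        assert history_weight(ens.histories[0], IndelModel(), tree3) == 1.0

    def test_single_event_weight_is_rate_pmf_time(self, tree3):
        blk = AlnBlock(("A", "B", "C"), ("AA", "AA", "--"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        model = IndelModel()
        f2 = float(model.length.pmf(2))
        weights = sorted(
            history_weight(h, model, tree3) for h in ens.histories
        )
        # deletion on C (t=0.3) and insertion on the stem (t=0.1)
        assert weights == pytest.approx(
            sorted([0.0625 * f2 * 0.3, 0.0625 * f2 * 0.1]))

    def test_zero_length_branch_gives_zero_weight(self):
        tree = tree_from_newick("((A:0.1,B:0.2):0.0,C:0.3);")
        blk = AlnBlock(("A", "B", "C"), ("-", "-", "A"))
        ens = enumerate_parsimonious_histories(blk, tree)
        ws = {
            tree.label[h.events[0].branch] or "stem":
                history_weight(h, IndelModel(), tree)
            for h in ens.histories
        }
        assert ws["stem"] == 0.0 and ws["C"] > 0

    def test_extra_event_strictly_lowers_weight(self, tree3):
        """Adding one event multiplies the weight by rate*f*t < 1."""
        from alignerr.histories import IndelEvent, IndelHistory

        e1 = IndelEvent("deletion", 1, (0,), (0, 2), 2)
        e2 = IndelEvent("deletion", 2, (1,), (2, 3), 1)
        model = IndelModel()
        w1 = history_weight(IndelHistory((e1,)), model, tree3)
        w2 = history_weight(IndelHistory((e1, e2)), model, tree3)
        assert 0 < w2 < w1


class TestExpectedCounts:
    def test_single_history_counts_are_event_counts(self, tree3):
        blk = AlnBlock(("A", "B", "C"), ("AA", "AA", "--"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        one = weight_ensemble(
            ens, IndelModel(ins_rate=0.0, del_rate=0.0625), tree3)
        counts = expected_indel_counts(one)
        assert (counts.insertions, counts.deletions) == (0.0, 1.0)

    def test_equal_weights_average_evenly(self, tree3):
        blk = AlnBlock(("A", "B", "C"), ("AA", "AA", "--"))
        ens = enumerate_parsimonious_histories(blk, tree3)
        ens.weights = [1.0, 1.0]
        counts = expected_indel_counts(ens)
        assert counts.insertions == counts.deletions == 0.5

    def test_branch_length_weighting(self, tree3):
        """Gap only in C with T_C=0.3, stem 0.1: deletion carries 3/4 of
        the probability mass."""
        blk = AlnBlock(("A", "B", "C"), ("AA", "AA", "--"))
        ens = weight_ensemble(
            enumerate_parsimonious_histories(blk, tree3), IndelModel(), tree3)
        counts = expected_indel_counts(ens)
        assert counts.deletions == pytest.approx(0.75)
        assert counts.insertions == pytest.approx(0.25)


class TestMisestimation:
    @pytest.mark.parametrize(
        "rec,tr,expect",
        [
            ((3, 1), (2, 2), (0, 2, 2)),
            ((0, 2), (1, 1), (0, 2, -2)),
            ((2, 2), (2, 2), (0, 0, 0)),
        ],
    )
    def test_printed_formulas(self, rec, tr, expect):
        m = misestimation_measures(
            IndelCounts(insertions=tr[1], deletions=tr[0]),
            IndelCounts(insertions=rec[1], deletions=rec[0]),
        )
        assert (m.ordinary_difference, m.l1_distance, m.deletion_bias) == expect

    @given(
        st.tuples(*[st.floats(0, 10, allow_nan=False) for _ in range(4)])
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_l1_dominates_other_measures(self, vals):
        ti, td, ri, rd = vals
        m = misestimation_measures(IndelCounts(ti, td), IndelCounts(ri, rd))
        assert m.l1_distance >= abs(m.ordinary_difference) - 1e-12
        assert m.l1_distance >= abs(m.deletion_bias) - 1e-12
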