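"""Error classification: decision table, deltas, reverses, tallies."""

import pytest

from alignerr.classify import (
    BlockDelta,
    Evt,
    classify_block,
    classify_block_pair,
    diagnose_and_tally,
    SegmentDiagnosis,
)

from tests._fixtures import REVERSE_OF, classify_fixture, iter_fixtures


def _evt(kind, branch, length, lo=0):
    return Evt(kind, branch, length, (lo, lo + length))


class TestDecisionTable:
    """Unit checks of the rules on synthetic event deltas (tree3: node ids
    0 root, 1 = AB stem, 2 = A, 3 = B, 4 = C)."""

    def test_repositioned_event_is_shift(self, tree3):
        d = BlockDelta((_evt("deletion", 2, 3, 0),),
                       (_evt("deletion", 2, 3, 5),))
        assert classify_block(d, tree3) == "shift"

    def test_same_branch_same_type_merge(self, tree3):
        d = BlockDelta(
            (_evt("deletion", 2, 2, 0), _evt("deletion", 2, 3, 4)),
            (_evt("deletion", 2, 5, 0),))
        assert classify_block(d, tree3) == "merge_same_type"

    def test_same_branch_opposite_type_merge(self, tree3):
        d = BlockDelta(
            (_evt("insertion", 2, 2, 0), _evt("deletion", 2, 6, 3)),
            (_evt("deletion", 2, 4, 0),))
        assert classify_block(d, tree3) == "merge_opposite_type"

    def test_vanishing_pair_is_purge(self, tree3):
        d = BlockDelta(
            (_evt("insertion", 2, 3, 0), _evt("deletion", 2, 3, 4)), ())
        assert classify_block(d, tree3) == "purge"

    def test_appearing_pair_is_ex_nihilo(self, tree3):
        d = BlockDelta(
            (), (_evt("insertion", 2, 3, 0), _evt("deletion", 2, 3, 4)))
        assert classify_block(d, tree3) == "ex_nihilo"

    def test_one_to_two_same_branch_is_split(self, tree3):
        d = BlockDelta(
            (_evt("deletion", 2, 5, 0),),
            (_evt("deletion", 2, 2, 0), _evt("deletion", 2, 3, 4)))
        assert classify_block(d, tree3) == "split"

    def test_parent_child_same_type_is_v_merge(self, tree3):
        # deletions on A (node 2) and the AB stem (node 1) -> one on the stem
        d = BlockDelta(
            (_evt("deletion", 2, 2, 0), _evt("deletion", 1, 3, 2)),
            (_evt("deletion", 1, 5, 0),))
        assert classify_block(d, tree3) == "v_merge"
        rev = BlockDelta(d.events_rec, d.events_true)
        assert classify_block(rev, tree3) == "v_split"

    def test_sibling_insertions_collapsed_is_CII(self, tree3):
        # insertions on A and B -> one on the AB stem
        d = BlockDelta(
            (_evt("insertion", 2, 3, 0), _evt("insertion", 3, 3, 0)),
            (_evt("insertion", 1, 3, 0),))
        assert classify_block(d, tree3) == "CII"
        rev = BlockDelta(d.events_rec, d.events_true)
        assert classify_block(rev, tree3) == "CSII"

    def test_partial_collapse_is_iCII(self, tree3):
        d = BlockDelta(
            (_evt("insertion", 2, 5, 0), _evt("insertion", 3, 3, 0)),
            (_evt("insertion", 1, 3, 0), _evt("insertion", 2, 2, 3)))
        assert classify_block(d, tree3) == "iCII"
        rev = BlockDelta(d.events_rec, d.events_true)
        assert classify_block(rev, tree3) == "iCSII"

    def test_unmatched_delta_is_complex(self, tree3):
        d = BlockDelta(
            (_evt("deletion", 2, 2, 0),),
            (_evt("insertion", 4, 5, 40), _evt("deletion", 3, 1, 50),
             _evt("deletion", 1, 2, 60)))
        assert classify_block(d, tree3) == "complex"

    def test_gapless_context_empty_delta(self, tree3):
        assert classify_block(BlockDelta((), ()), tree3) == "complex"

    def test_unchanged_neighbor_cancels_before_counting(self, tree3):
        """An unrelated event present identically on both sides must not
        break the two-to-one merge rule."""
        bystander = _evt("deletion", 4, 2, 40)
        d = BlockDelta(
            (_evt("deletion", 2, 2, 0), _evt("deletion", 2, 3, 4), bystander),
            (_evt("deletion", 2, 5, 0), bystander))
        assert classify_block(d, tree3) == "merge_same_type"


class TestPairRescue:
    def test_merge_plus_shift_pairing(self, tree3):
        """A merged gap that also moved: the joint delta matches the merge
        rule and the second block reads as the repositioning."""
        joint = BlockDelta(
            (_evt("deletion", 2, 2, 0), _evt("deletion", 2, 3, 4)),
            (_evt("deletion", 2, 5, 20),))
        out = classify_block_pair(
            BlockDelta((), ()), BlockDelta((), ()), joint, tree3)
        assert out == ("merge_same_type", "shift")

    def test_unsplittable_joint_delta_returns_none(self, tree3):
        joint = BlockDelta(
            (_evt("deletion", 2, 2, 0),),
            (_evt("insertion", 4, 7, 30),))
        assert classify_block_pair(
            BlockDelta((), ()), BlockDelta((), ()), joint, tree3) is None


class TestGroundTruthRecovery:
    @pytest.mark.parametrize(
        "error_type",
        ["shift", "split", "ex_nihilo", "CSII", "iCII", "purge",
         "merge_opposite_type"],
    )
    def test_injected_label_recovered(self, error_type):
        n = ok = 0
        for tree, true_msa, rec, label in iter_fixtures(
                8, seed=31, types=[error_type]):
            n += 1
            if classify_fixture(tree, true_msa, rec) == {label}:
                ok += 1
        assert n >= 4 and ok == n

    def test_reverse_direction_yields_reverse_label(self):
        """Swapping true/rec flips each label to its listed reverse."""
        for typ in ("split", "ex_nihilo", "CSII", "shift"):
            for tree, true_msa, rec, label in iter_fixtures(
                    4, seed=53, types=[typ]):
                got = classify_fixture(tree, true_msa, rec, swap=True)
                assert got == {REVERSE_OF[label]}

    def test_labels_invariant_to_sequence_order(self):
        import numpy as np

        from alignerr.msa import Msa

        for tree, true_msa, rec, label in iter_fixtures(2, seed=71,
                                                        types=["shift"]):
            order = np.random.default_rng(0).permutation(len(rec.names))
            rec2 = Msa(tuple(rec.names[i] for i in order),
                       tuple(rec.rows[i] for i in order))
            assert classify_fixture(tree, true_msa, rec2) == {label}


class TestTally:
    def _diag(self, labels, cls, paired=False):
        return SegmentDiagnosis(0, labels, cls, paired=paired)

    def test_uniform_single_type(self):
        df = diagnose_and_tally(
            [self._diag(["shift"], "single-type")] * 10)
        row = df[df.error_type == "shift"].iloc[0]
        assert row["count"] == 10 and row["percent"] == 100.0

    def test_mixture_and_complex_rows(self):
        diags = (
            [self._diag(["shift"], "single-type")] * 5
            + [self._diag(["shift", "merge_same_type"], "mixture")] * 3
            + [self._diag(["merge_same_type", "shift"], "mixture", paired=True)]
            + [self._diag(["complex"], "complex")]
        )
        df = diagnose_and_tally(diags).set_index("error_type")
        assert df.loc["mixture", "count"] == 4
        assert df.loc["(paired)", "count"] == 1
        assert df.loc["complex", "count"] == 1
        assert df.loc["total", "count"] == 10
        named = df.drop(index=["(paired)", "total"])
        assert named["percent"].sum() == pytest.approx(100.0)
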