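"""Associate position-shift blocks with named alignment-error types.

The idea: infer indel events independently from the true and the
reconstructed alignment of an erroneous segment (via the parsimonious
history machinery, taking each gapped segment's maximum-weight history as
representative), restrict both event sets to a window around one
position-shift block, and read the error type off the change between the
two sets.  A repositioned event is a *shift*; two events fusing into one on
the same branch is a *merge*; an equal-size insertion/deletion pair
vanishing is a *purge* (appearing: *ex-nihilo*); same-type events moving to
a common ancestral branch are *vertical* merges/splits; independent
insertions aligned as one ancestral insertion are collapses (CII/iCII, with
CSII/iCSII as their spurious-creation reverses).  Whatever matches no rule
is *complex* — the honest bucket for entangled errors.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from .errors import AlignerrError, IntractableSegmentError
from .histories import enumerate_parsimonious_histories, weight_ensemble
from .msa import AlnBlock, GAP
from .phylo import PhyloTree
from .segments import SegmentPair, SegmentSeries
from .shiftmap import (
    SeparationMetrics,
    ShiftBlock,
    build_position_shift_map,
    partition_shift_blocks,
    separation_metrics,
)
from .sim import IndelModel

NONCOMPLEX_LABELS = (
    "shift", "merge_same_type", "merge_opposite_type", "purge", "split",
    "ex_nihilo", "v_merge", "v_split", "CII", "CSII", "iCII", "iCSII",
    "other_noncomplex",
)


@dataclass(frozen=True)
class Evt:
    """An inferred event in segment-local coordinates."""

    kind: str
    branch: int
    length: int
    span: tuple[int, int]

    @property
    def sig(self):
        return (self.kind, self.branch, self.length)


@dataclass(frozen=True)
class BlockDelta:
    events_true: tuple[Evt, ...]
    events_rec: tuple[Evt, ...]


# ---------------------------------------------------------------------------
# Representative events of a segment side
# ---------------------------------------------------------------------------

def _runs_of(block: AlnBlock):
    """Alternating presence-pattern runs over a segment block, gapless
    stretches included: list of (start, stop, gapped?)."""
    n_cols = len(block.rows[0]) if block.rows else 0
    runs = []
    prev = None
    start = 0
    for j in range(n_cols):
        key = tuple(r[j] != GAP for r in block.rows)
        if key != prev:
            if prev is not None:
                runs.append((start, j, not all(prev)))
            prev, start = key, j
    if prev is not None:
        runs.append((start, n_cols, not all(prev)))
    return runs


def representative_events(block: AlnBlock, tree: PhyloTree,
                          model: IndelModel, **caps) -> list[Evt]:
    """Max-weight parsimonious events of every gapped stretch of ``block``,
    in block-local coordinates."""
    out = []
    from .msa import gap_segmentation

    for a, b in gap_segmentation(block).gapped_spans:
        sub = AlnBlock(block.names, tuple(r[a:b] for r in block.rows))
        ens = enumerate_parsimonious_histories(sub, tree, **caps)
        ens = weight_ensemble(ens, model, tree)
        rep = ens.representative()
        for e in rep.events:
            out.append(
                Evt(e.kind, e.branch, e.length, (a + e.span[0], a + e.span[1]))
            )
    return out


# ---------------------------------------------------------------------------
# Block deltas
# ---------------------------------------------------------------------------

def _window(runs, lo: int, hi: int) -> tuple[int, int]:
    """[lo, hi) extended to one whole run further on each side."""
    a, b = lo, hi
    starts = [r[0] for r in runs]
    for s, e, _ in runs:
        if s <= lo < e:
            a = s
        if s < hi <= e:
            b = e
    # extend one run beyond
    for i, (s, e, _) in enumerate(runs):
        if s == a and i > 0:
            a = runs[i - 1][0]
            break
    for i, (s, e, _) in enumerate(runs):
        if e == b and i + 1 < len(runs):
            b = runs[i + 1][1]
            break
    return a, b


def block_event_delta(series: SegmentSeries, seg: SegmentPair,
                      block: ShiftBlock, tree: PhyloTree,
                      model: IndelModel = IndelModel(),
                      events_true: list[Evt] | None = None,
                      events_rec: list[Evt] | None = None,
                      **caps) -> BlockDelta:
    """Both representative event sets restricted to the block's vicinity.

    The window is the block's column span widened by one pattern-run on each
    side (on the reconstructed side), mapped onto the true side through the
    block's residues.  Precomputed whole-segment event lists may be passed to
    avoid re-enumeration.
    """
    tblock = series.true_block(seg)
    rblock = series.rec_block(seg)
    if events_true is None:
        events_true = representative_events(tblock, tree, model, **caps)
    if events_rec is None:
        events_rec = representative_events(rblock, tree, model, **caps)

    rec_runs = _runs_of(rblock)
    lo, hi = block.col_span
    ra, rb = _window(rec_runs, lo, hi - 1 + 1)

    # map the rec window onto true columns via residue positions
    true_pos: list[int] = []
    for rrow, trow in zip(rblock.rows, tblock.rows):
        pr = [j for j, ch in enumerate(rrow) if ch != GAP]
        pt = [j for j, ch in enumerate(trow) if ch != GAP]
        for j_r, j_t in zip(pr, pt):
            if ra <= j_r < rb:
                true_pos.append(j_t)
    if true_pos:
        ta, tb = min(true_pos), max(true_pos) + 1
        ta, tb = _window(_runs_of(tblock), ta, tb)
    else:
        ta, tb = 0, len(tblock.rows[0])

    keep_r = tuple(e for e in events_rec if e.span[0] < rb and e.span[1] > ra)
    keep_t = tuple(e for e in events_true if e.span[0] < tb and e.span[1] > ta)
    return BlockDelta(keep_t, keep_r)


# ---------------------------------------------------------------------------
# The decision table
# ---------------------------------------------------------------------------

def _independent(tree: PhyloTree, b1: int, b2: int) -> bool:
    return not tree.is_ancestor(b1, b2) and not tree.is_ancestor(b2, b1)


def _common_ancestral(tree: PhyloTree, anc: int, b1: int, b2: int) -> bool:
    return anc not in (b1, b2) and tree.is_ancestor(anc, b1) and tree.is_ancestor(anc, b2)


def _related(tree: PhyloTree, b1: int, b2: int) -> bool:
    """Parent/child or sibling branches."""
    return (
        tree.parent[b1] == b2 or tree.parent[b2] == b1
        or tree.parent[b1] == tree.parent[b2]
    )


def _merge_target(tree: PhyloTree, b1: int, b2: int) -> int | None:
    """The branch a vertical merge lands on: the more ancestral of a
    parent/child pair, or the stem above siblings."""
    if tree.parent[b1] == b2:
        return b2
    if tree.parent[b2] == b1:
        return b1
    if tree.parent[b1] == tree.parent[b2] and tree.parent[b1] != 0:
        return tree.parent[b1]
    return None


def classify_block(delta: BlockDelta, tree: PhyloTree) -> str:
    """Deterministic label from the event delta (see the decision table)."""
    T = list(delta.events_true)
    R = list(delta.events_rec)

    # cancel events unchanged between the two sides
    for e in list(T):
        for f in list(R):
            if e == f:
                T.remove(e)
                R.remove(f)
                break

    if not T and not R:
        return "complex"  # a block with no event change is unexplained

    # 1. same events, different positions
    if Counter(e.sig for e in T) == Counter(e.sig for e in R):
        return "shift"

    # neighbors caught in the window merely repositioned by the block's move
    # cancel pairwise by signature; the block's own change remains
    for e in list(T):
        for f in list(R):
            if e.sig == f.sig:
                T.remove(e)
                R.remove(f)
                break

    # 2. two events -> one on the same branch
    if len(T) == 2 and len(R) == 1:
        (e1, e2), (r,) = T, R
        if e1.branch == e2.branch == r.branch:
            if e1.kind == e2.kind == r.kind and e1.length + e2.length == r.length:
                return "merge_same_type"
            if e1.kind != e2.kind and abs(e1.length - e2.length) == r.length:
                return "merge_opposite_type"

    # 3. an insertion/deletion pair of equal length vanishes
    if len(T) == 2 and not R:
        e1, e2 = T
        if e1.kind != e2.kind and e1.length == e2.length:
            return "purge"

    # 4. one event -> two on the same branch
    if len(T) == 1 and len(R) == 2:
        (e,), (r1, r2) = T, R
        if r1.branch == r2.branch == e.branch:
            if r1.kind == r2.kind == e.kind and r1.length + r2.length == e.length:
                return "split"
            if r1.kind != r2.kind and abs(r1.length - r2.length) == e.length:
                return "split"

    # 5. an insertion/deletion pair of equal length appears
    if not T and len(R) == 2:
        r1, r2 = R
        if r1.kind != r2.kind and r1.length == r2.length:
            return "ex_nihilo"

    # 6. same-type events on related branches -> their common ancestral branch
    if len(T) == 2 and len(R) == 1:
        (e1, e2), (r,) = T, R
        if (e1.kind == e2.kind == r.kind and _related(tree, e1.branch, e2.branch)
                and _merge_target(tree, e1.branch, e2.branch) == r.branch
                and e1.length + e2.length == r.length):
            return "v_merge"
    if len(T) == 1 and len(R) == 2:
        (e,), (r1, r2) = T, R
        if (r1.kind == r2.kind == e.kind and _related(tree, r1.branch, r2.branch)
                and _merge_target(tree, r1.branch, r2.branch) == e.branch
                and r1.length + r2.length == e.length):
            return "v_split"

    # 7. independent insertions collapsed onto a common ancestral branch
    if len(T) == 2 and len(R) == 1:
        (e1, e2), (r,) = T, R
        if (e1.kind == e2.kind == r.kind == "insertion"
                and _independent(tree, e1.branch, e2.branch)
                and _common_ancestral(tree, r.branch, e1.branch, e2.branch)):
            return "CII"
    if len(T) == 1 and len(R) == 2:
        (e,), (r1, r2) = T, R
        if (r1.kind == r2.kind == e.kind == "insertion"
                and _independent(tree, r1.branch, r2.branch)
                and _common_ancestral(tree, e.branch, r1.branch, r2.branch)):
            return "CSII"

    # 8. incomplete collapses: ancestral insertion plus residual events
    if len(T) == 2 and 2 <= len(R) <= len(T) + 1:
        ins_t = [e for e in T if e.kind == "insertion"]
        if len(ins_t) == 2 and _independent(tree, ins_t[0].branch, ins_t[1].branch):
            for r in R:
                if (r.kind == "insertion"
                        and _common_ancestral(tree, r.branch, ins_t[0].branch,
                                              ins_t[1].branch)):
                    return "iCII"
    if len(R) == 2 and 2 <= len(T) <= len(R) + 1:
        ins_r = [e for e in R if e.kind == "insertion"]
        if len(ins_r) == 2 and _independent(tree, ins_r[0].branch, ins_r[1].branch):
            for e in T:
                if (e.kind == "insertion"
                        and _common_ancestral(tree, e.branch, ins_r[0].branch,
                                              ins_r[1].branch)):
                    return "iCSII"

    # 9. small unclassified deltas with overlapping spans
    if abs(len(T) - len(R)) <= 1 and 1 <= len(T) + len(R) <= 5:
        spans_t = [e.span for e in T]
        spans_r = [e.span for e in R]
        if not spans_t or not spans_r or any(
            a0 < b1 and a1 > b0 for a0, a1 in spans_t for b0, b1 in spans_r
        ):
            return "other_noncomplex"
    return "complex"


def classify_block_pair(deltaA: BlockDelta, deltaB: BlockDelta,
                        joint: BlockDelta, tree: PhyloTree):
    """Try to explain two adjacent unclassified blocks as a pair of named
    errors (e.g. a merge whose merged gap also moved: "merge + shift").

    Returns an ordered (label, label) pair or None.  The joint delta is
    first matched whole (a merge-like joint delta with two blocks reads as
    the named error plus the repositioning); otherwise every bipartition of
    the joint events is tried.
    """
    whole = classify_block(joint, tree)
    if whole in NONCOMPLEX_LABELS and whole != "other_noncomplex":
        return (whole, "shift")

    T, R = list(joint.events_true), list(joint.events_rec)
    if len(T) + len(R) > 6:
        return None
    for t_mask in range(1 << len(T)):
        t1 = [e for i, e in enumerate(T) if t_mask >> i & 1]
        t2 = [e for i, e in enumerate(T) if not t_mask >> i & 1]
        for r_mask in range(1 << len(R)):
            r1 = [e for i, e in enumerate(R) if r_mask >> i & 1]
            r2 = [e for i, e in enumerate(R) if not r_mask >> i & 1]
            if not (t1 or r1) or not (t2 or r2):
                continue
            la = classify_block(BlockDelta(tuple(t1), tuple(r1)), tree)
            lb = classify_block(BlockDelta(tuple(t2), tuple(r2)), tree)
            if (la in NONCOMPLEX_LABELS and lb in NONCOMPLEX_LABELS
                    and la != "complex" and lb != "complex"
                    and "other_noncomplex" not in (la, lb)):
                return (la, lb)
    return None


# ---------------------------------------------------------------------------
# Per-segment diagnosis and tallies
# ---------------------------------------------------------------------------

@dataclass
class SegmentDiagnosis:
    """Everything measured about one erroneous segment."""

    segment_index: int
    block_labels: list
    segment_class: str  # "single-type" | "mixture" | "complex" | "no-blocks"
    paired: bool = False
    category: str | None = None  # D/I/S
    metrics: SeparationMetrics | None = None
    misestimation: object | None = None


def label_blocks(series: SegmentSeries, seg: SegmentPair, tree: PhyloTree,
                 model: IndelModel = IndelModel(), **caps):
    """Shift blocks of a segment with their error labels (pair rescue
    included).  Returns (blocks, labels, paired_flags)."""
    smap = build_position_shift_map(series, seg)
    blocks = partition_shift_blocks(smap, tree)
    if not blocks:
        return [], [], []
    try:
        ev_t = representative_events(series.true_block(seg), tree, model, **caps)
        ev_r = representative_events(series.rec_block(seg), tree, model, **caps)
    except (IntractableSegmentError, AlignerrError):
        return blocks, ["complex"] * len(blocks), [False] * len(blocks)

    deltas = []
    labels = []
    for blk in blocks:
        try:
            d = block_event_delta(series, seg, blk, tree, model,
                                  events_true=ev_t, events_rec=ev_r, **caps)
            deltas.append(d)
            labels.append(classify_block(d, tree))
        except AlignerrError:
            deltas.append(BlockDelta((), ()))
            labels.append("complex")
    paired = [False] * len(blocks)

    # pair rescue over adjacent unclassified blocks
    for i in range(len(blocks) - 1):
        if labels[i] == "complex" and labels[i + 1] == "complex":
            joint = BlockDelta(
                tuple(dict.fromkeys(deltas[i].events_true + deltas[i + 1].events_true)),
                tuple(dict.fromkeys(deltas[i].events_rec + deltas[i + 1].events_rec)),
            )
            pair = classify_block_pair(deltas[i], deltas[i + 1], joint, tree)
            if pair is not None:
                labels[i], labels[i + 1] = pair
                paired[i] = paired[i + 1] = True
    return blocks, labels, paired


def diagnose_segment(series: SegmentSeries, seg: SegmentPair,
                     tree: PhyloTree, model: IndelModel = IndelModel(),
                     **caps) -> SegmentDiagnosis:
    blocks, labels, paired = label_blocks(series, seg, tree, model, **caps)
    metrics = separation_metrics(blocks)
    if not labels:
        cls = "no-blocks"
    elif any(l == "complex" for l in labels):
        cls = "complex"
    elif len(set(labels)) == 1 and not any(paired):
        cls = "single-type"
    else:
        cls = "mixture"
    return SegmentDiagnosis(
        segment_index=seg.index,
        block_labels=labels,
        segment_class=cls,
        paired=any(paired),
        metrics=metrics,
    )


_TALLY_ROWS = (
    "shift", "merge_same_type", "merge_opposite_type", "purge", "split",
    "ex_nihilo", "v_merge", "v_split", "CII", "iCII", "CSII", "iCSII",
    "other_noncomplex",
)


def diagnose_and_tally(diagnoses: list[SegmentDiagnosis]):
    """Frequency table over diagnosed segments.

    Single-type segments count under their label; segments mixing several
    non-complex labels count under Mixture (with the paired-error subset
    reported as the Paired sub-row); segments with any complex block count
    under Complex.  Percentages (over Total) sum to 100 excluding Paired.
    """
    import pandas as pd

    counts = {r: 0 for r in _TALLY_ROWS}
    mixture = complex_ = paired = 0
    total = 0
    for d in diagnoses:
        if d.segment_class == "no-blocks":
            continue
        total += 1
        if d.segment_class == "complex":
            complex_ += 1
        elif d.segment_class == "single-type":
            counts[d.block_labels[0]] += 1
        else:
            mixture += 1
            if d.paired:
                paired += 1
    rows = []
    for r in _TALLY_ROWS:
        rows.append((r, counts[r]))
    rows += [("mixture", mixture), ("(paired)", paired),
             ("complex", complex_), ("total", total)]
    df = pd.DataFrame(rows, columns=["error_type", "count"])
    df["percent"] = [
        100.0 * c / total if total and r != "(paired)" else
        (100.0 * c / total if total else 0.0)
        for r, c in zip(df["error_type"], df["count"])
    ]
    return df
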