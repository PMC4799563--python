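"""Chop a (true, reconstructed) MSA pair into correct and erroneous segments.

Anchor columns — columns that are gapless in both alignments and homologize
exactly the same residues — delimit the comparison: maximal runs of anchors
(plus inter-anchor regions where the alignments agree byte-for-byte in
canonical form) are *correct* segments, and the regions where the two
alignments disagree are *erroneous* segments.  The two labels strictly
alternate and together tile every sequence.

The downstream analyses all operate per erroneous segment; segments in which
either alignment shows an apparent indel run of more than 100 columns are
flagged intractable and excluded by :func:`tractability_filter`, mirroring
the screening used to keep the enumeration of indel histories affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InputError
from .msa import AlnBlock, Msa, gap_segmentation, has_long_indel

LONG_INDEL_THRESHOLD = 100


@dataclass(frozen=True)
class SegmentPair:
    """One segment of the alternating correct/erroneous series.

    Column intervals are 0-based half-open in each alignment; the
    residue-ordinal interval of every sequence is identical between the two
    alignments by construction (segments are delimited by shared anchors).
    """

    label: str  # "correct" | "erroneous"
    true_cols: tuple[int, int]
    rec_cols: tuple[int, int]
    residue_ivals: dict  # name -> (ordinal lo, ordinal hi), half-open
    n_true_gapped: int = 0  # true gapped segments overlapping this segment
    tractable: bool = True
    index: int = -1


@dataclass
class SegmentSeries:
    """Ordered segments of one (true, reconstructed) pair plus the parents."""

    true_msa: Msa
    rec_msa: Msa  # rows reordered to true_msa's name order
    segments: tuple[SegmentPair, ...]

    def erroneous(self, tractable_only: bool = False) -> list[SegmentPair]:
        out = [s for s in self.segments if s.label == "erroneous"]
        if tractable_only:
            out = [s for s in out if s.tractable]
        return out

    @property
    def n_erroneous(self) -> int:
        return len(self.erroneous())

    @property
    def n_excluded(self) -> int:
        return sum(1 for s in self.erroneous() if not s.tractable)

    def true_block(self, seg: SegmentPair) -> AlnBlock:
        a, b = seg.true_cols
        return AlnBlock(self.true_msa.names, tuple(r[a:b] for r in self.true_msa.rows))

    def rec_block(self, seg: SegmentPair) -> AlnBlock:
        a, b = seg.rec_cols
        return AlnBlock(self.rec_msa.names, tuple(r[a:b] for r in self.rec_msa.rows))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "index\tlabel\ttrue_start\ttrue_end\trec_start\trec_end\t"
                "n_true_gapped\ttractable\n"
            )
            for s in self.segments:
                fh.write(
                    f"{s.index}\t{s.label}\t{s.true_cols[0]}\t{s.true_cols[1]}\t"
                    f"{s.rec_cols[0]}\t{s.rec_cols[1]}\t{s.n_true_gapped}\t"
                    f"{int(s.tractable)}\n"
                )


def _reorder_like(ref: Msa, other: Msa) -> Msa:
    if ref.names == other.names:
        return other
    if set(ref.names) != set(other.names):
        raise InputError("the two MSAs name different sequences")
    order = [other.names.index(n) for n in ref.names]
    return Msa(ref.names, tuple(other.rows[i] for i in order))


def find_anchor_columns(true_msa: Msa, rec_msa: Msa) -> list[tuple[int, int]]:
    """Matched (true column, rec column) pairs of shared gapless columns.

    A column qualifies when it is gapless in both alignments and pairs the
    same residue ordinal of every sequence; the result is strictly
    increasing in both coordinates.  Raises ``InputError`` when the ungapped
    rows differ (the inputs are then not alignments of the same sequences).
    """
    rec_msa = _reorder_like(true_msa, rec_msa)
    if true_msa.ungapped() != rec_msa.ungapped():
        raise InputError("ungapped sequences differ between the two MSAs")

    def gapless_keys(m: Msa) -> dict[tuple, int]:
        ords = m.column_ordinals()
        out = {}
        for j in range(m.n_cols):
            col = [ords[i][j] for i in range(m.n_rows)]
            if all(o is not None for o in col):
                out[tuple(col)] = j
        return out

    keys_t = gapless_keys(true_msa)
    keys_r = gapless_keys(rec_msa)
    anchors = [(j, keys_r[k]) for k, j in keys_t.items() if k in keys_r]
    anchors.sort()
    return anchors


def partition_into_segments(true_msa: Msa, rec_msa: Msa) -> SegmentSeries:
    """Build the alternating correct/erroneous segment series of a pair.

    Both alignments should be canonical; inter-anchor regions that agree
    byte-for-byte are absorbed into the flanking correct segment, regions
    that differ become erroneous segments delimited by the nearest anchors
    (or the alignment termini at the ends).
    """
    rec_msa = _reorder_like(true_msa, rec_msa)
    anchors = find_anchor_columns(true_msa, rec_msa)

    def region_equal(t0, t1, r0, r1) -> bool:
        if (t1 - t0) != (r1 - r0):
            return False
        return all(
            rt[t0:t1] == rr[r0:r1] for rt, rr in zip(true_msa.rows, rec_msa.rows)
        )

    # Boundary markers: (true col, rec col) before/after each unit.
    marks = [(0, 0)] + [(i + 1, j + 1) for i, j in anchors] + [
        (true_msa.n_cols, rec_msa.n_cols)
    ]
    # Units: anchor k sits between region k and region k+1.
    n_regions = len(anchors) + 1

    def region_bounds(k):
        t0 = 0 if k == 0 else anchors[k - 1][0] + 1
        r0 = 0 if k == 0 else anchors[k - 1][1] + 1
        t1 = true_msa.n_cols if k == len(anchors) else anchors[k][0]
        r1 = rec_msa.n_cols if k == len(anchors) else anchors[k][1]
        return t0, t1, r0, r1

    # Walk units left to right, merging correct material.
    raw: list[tuple[str, int, int, int, int]] = []  # (label, t0,t1,r0,r1)

    def push(label, t0, t1, r0, r1):
        if t1 == t0 and r1 == r0:
            return
        if raw and raw[-1][0] == label:
            old = raw.pop()
            raw.append((label, old[1], t1, old[3], r1))
        else:
            raw.append((label, t0, t1, r0, r1))

    for k in range(n_regions):
        t0, t1, r0, r1 = region_bounds(k)
        lab = "correct" if region_equal(t0, t1, r0, r1) else "erroneous"
        push(lab, t0, t1, r0, r1)
        if k < len(anchors):
            i, j = anchors[k]
            push("correct", i, i + 1, j, j + 1)

    true_res = _cum_residues(true_msa)
    true_gapped = gap_segmentation(true_msa).gapped_spans
    segs = []
    for idx, (lab, t0, t1, r0, r1) in enumerate(raw):
        ivals = {
            n: (true_res[i][t0], true_res[i][t1])
            for i, n in enumerate(true_msa.names)
        }
        n_gap = sum(1 for a, b in true_gapped if a < t1 and b > t0)
        segs.append(
            SegmentPair(
                label=lab, true_cols=(t0, t1), rec_cols=(r0, r1),
                residue_ivals=ivals, n_true_gapped=n_gap, index=idx,
            )
        )
    return SegmentSeries(true_msa, rec_msa, tuple(segs))


def _cum_residues(m: Msa) -> list[list[int]]:
    """Per row: residues strictly before each column (length n_cols+1)."""
    out = []
    for r in m.rows:
        c = [0]
        for ch in r:
            c.append(c[-1] + (ch != "-"))
        out.append(c)
    return out


def tractability_filter(
    series: SegmentSeries, threshold: int = LONG_INDEL_THRESHOLD
) -> tuple[SegmentSeries, int]:
    """Flag erroneous segments containing apparent indel runs > ``threshold``.

    A segment is excluded when *either* alignment shows a single-row gap run
    of more than ``threshold`` columns inside the segment.  Returns the
    updated series and the number of newly excluded segments.
    """
    new_segs = []
    excluded = 0
    for s in series.segments:
        if s.label != "erroneous":
            new_segs.append(s)
            continue
        long_t = has_long_indel(series.true_msa, s.true_cols, threshold)
        long_r = has_long_indel(series.rec_msa, s.rec_cols, threshold)
        keep = not (long_t or long_r)
        if not keep:
            excluded += 1
        new_segs.append(replace(s, tractable=keep))
    return SegmentSeries(series.true_msa, series.rec_msa, tuple(new_segs)), excluded
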