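"""Position-shift maps and their partition into phylogeny-guided blocks.

For each residue of an erroneous segment the *position-shift* is its column
in the reconstructed alignment minus its column in the true alignment, both
counted segment-locally so that the flanking background is always shift 0.
Drawing the shifts on one of the two alignments visualizes exactly where the
reconstruction moved residues; lumping same-shift residues into *blocks*
(contiguous along the alignment and connected on the tree) turns the map
into a move count: each non-background block is one elementary move
separating the two alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .msa import AlnBlock
from .phylo import PhyloTree
from .segments import SegmentPair, SegmentSeries

BLOCK_STEPS_THRESHOLD = 5   # "many block-wise moves"
SITE_STEPS_THRESHOLD = 30   # "many site-wise moves"
LONG_BLOCK_THRESHOLD = 30   # "long block"


@dataclass
class ShiftMap:
    """Per-residue shifts of one erroneous segment, drawn on one side.

    ``shifts[i][j]`` is the integer shift of row i's residue in column j of
    the *target* alignment block, or None where the target shows a gap.
    Positive shift means the reconstruction pushed the residue rightward.
    """

    target: str  # "reconstructed" | "true"
    names: tuple[str, ...]
    shifts: tuple[tuple, ...]
    target_block: AlnBlock

    @property
    def n_cols(self) -> int:
        return len(self.shifts[0]) if self.shifts else 0

    def is_zero(self) -> bool:
        return all(s in (0, None) for row in self.shifts for s in row)

    def to_tsv(self, path) -> None:
        """Matrix rendering; positions are reported 1-based, gaps as '.'."""
        with open(path, "w") as fh:
            fh.write("name\t" + "\t".join(str(j + 1) for j in range(self.n_cols)) + "\n")
            for n, row in zip(self.names, self.shifts):
                fh.write(n + "\t" + "\t".join("." if s is None else str(s) for s in row) + "\n")

    def render(self) -> str:
        """Compact ASCII rendering: one char per cell (hex for |s| > 9)."""
        def cell(s):
            if s is None:
                return "."
            if s == 0:
                return "0"
            c = "%x" % min(abs(s), 15)
            return c.upper() if s < 0 else c

        return "\n".join(
            f"{n:>12s} " + "".join(cell(s) for s in row)
            for n, row in zip(self.names, self.shifts)
        )


def build_position_shift_map(
    series: SegmentSeries, seg: SegmentPair, target: str = "reconstructed",
    allow_trivial: bool = False,
) -> ShiftMap:
    """Shift map of one erroneous segment, drawn on the target alignment.

    Shifts use segment-local column numbering so the background is 0
    regardless of length differences upstream of the segment.
    """
    if seg.label != "erroneous" and not allow_trivial:
        raise DomainError("shift map of a correct segment is identically zero")
    if target not in ("reconstructed", "true"):
        raise DomainError(f"unknown target {target!r}")

    tblock = series.true_block(seg)
    rblock = series.rec_block(seg)
    # the shift of a residue is its reconstructed column minus its true
    # column; the target only chooses the canvas the values are drawn on
    tgt = rblock if target == "reconstructed" else tblock

    shifts = []
    for i in range(len(tgt.rows)):
        pos_r = [j for j, ch in enumerate(rblock.rows[i]) if ch != "-"]
        pos_t = [j for j, ch in enumerate(tblock.rows[i]) if ch != "-"]
        assert len(pos_r) == len(pos_t), "segment residue intervals must agree"
        row = [None] * tgt.n_cols
        for pr, pt in zip(pos_r, pos_t):
            row[pr if target == "reconstructed" else pt] = pr - pt
        shifts.append(tuple(row))
    return ShiftMap(target, tgt.names, tuple(shifts), tgt)


@dataclass
class ShiftBlock:
    """Maximal same-shift region, contiguous along alignment and phylogeny."""

    shift: int
    members: tuple  # (row index, target column) per residue
    rows: frozenset  # sequence names
    col_span: tuple[int, int]  # [min col, max col + 1) in the target block
    length: int  # distinct columns spanned

    def columns(self) -> set:
        return {c for _, c in self.members}


def _row_runs(smap: ShiftMap):
    """Per-row maximal runs of consecutive residues with equal non-zero shift."""
    runs = []
    for i, row in enumerate(smap.shifts):
        cols = [j for j, s in enumerate(row) if s is not None]
        cur: list[int] = []
        cur_s = None
        for j in cols:
            s = row[j]
            if s == cur_s and cur:
                cur.append(j)
            else:
                if cur and cur_s != 0:
                    runs.append((i, cur_s, cur))
                cur, cur_s = [j], s
        if cur and cur_s != 0:
            runs.append((i, cur_s, cur))
    return runs


def partition_shift_blocks(smap: ShiftMap, tree: PhyloTree) -> list[ShiftBlock]:
    """Partition a shift map into position-shift blocks.

    Two same-shift row runs merge when their column spans overlap in the
    target alignment and the rows are phylogenetically connected for the
    block: every other leaf inside the clade spanned by the two rows either
    carries the same shift in the overlap columns or has only gaps there.
    Background (shift 0) residues belong to no block.
    """
    runs = _row_runs(smap)
    n = len(runs)
    name_to_row = {nm: i for i, nm in enumerate(smap.names)}
    leaf_node = {nm: tree.node_of_leaf(nm) for nm in smap.names}

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    def conforms(row_i: int, shift: int, lo: int, hi: int) -> bool:
        """Row carries only ``shift`` (or gaps) in columns [lo, hi]."""
        r = smap.shifts[row_i]
        return all(r[j] is None or r[j] == shift for j in range(lo, hi + 1))

    for a in range(n):
        ia, sa, cols_a = runs[a]
        for b in range(a + 1, n):
            ib, sb, cols_b = runs[b]
            if sa != sb or ia == ib:
                continue
            lo = max(cols_a[0], cols_b[0])
            hi = min(cols_a[-1], cols_b[-1])
            if lo > hi:
                continue
            mrca = tree.mrca_node([leaf_node[smap.names[ia]], leaf_node[smap.names[ib]]])
            ok = True
            for node in tree.subtree_nodes(mrca):
                if not tree.is_leaf(node):
                    continue
                nm = tree.label[node]
                i = name_to_row.get(nm)
                if i is None or i in (ia, ib):
                    continue
                if not conforms(i, sa, lo, hi):
                    ok = False
                    break
            if ok:
                union(a, b)

    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)

    blocks = []
    for members in groups.values():
        shift = runs[members[0]][1]
        res = []
        cols = set()
        rows = set()
        for k in members:
            i, _, cs = runs[k]
            rows.add(smap.names[i])
            cols.update(cs)
            res.extend((i, c) for c in cs)
        blocks.append(
            ShiftBlock(
                shift=shift,
                members=tuple(sorted(res)),
                rows=frozenset(rows),
                col_span=(min(cols), max(cols) + 1),
                length=len(cols),
            )
        )
    blocks.sort(key=lambda b: (b.col_span, b.shift))
    return blocks


@dataclass(frozen=True)
class SeparationMetrics:
    """How far apart the two alignments of a segment are.

    ``n_blocks`` counts block-wise moves; ``total_path_length`` (the sum of
    block lengths in sites) counts site-wise moves; the flags apply the
    standard far-apart thresholds (>=5 blocks, >=30 sites, block >=30 long).
    """

    n_blocks: int
    total_path_length: int
    max_block_length: int

    @property
    def many_blocks(self) -> bool:
        return self.n_blocks >= BLOCK_STEPS_THRESHOLD

    @property
    def many_sites(self) -> bool:
        return self.total_path_length >= SITE_STEPS_THRESHOLD

    @property
    def long_block(self) -> bool:
        return self.max_block_length >= LONG_BLOCK_THRESHOLD


def separation_metrics(blocks: list[ShiftBlock]) -> SeparationMetrics:
    if not blocks:
        return SeparationMetrics(0, 0, 0)
    return SeparationMetrics(
        n_blocks=len(blocks),
        total_path_length=sum(b.length for b in blocks),
        max_block_length=max(b.length for b in blocks),
    )


def realign_by_shifts(smap: ShiftMap) -> AlnBlock:
    """Undo every block move at once: slide each residue by -shift.

    Residues that land on the same corrected column become one homology
    column; the result has the homology structure of the *other* alignment
    of the pair, which is the invariant the block decomposition rests on.
    """
    placed: dict[int, dict[int, str]] = {}
    sign = 1 if smap.target == "reconstructed" else -1
    for i, (row, srow) in enumerate(zip(smap.target_block.rows, smap.shifts)):
        for j, s in enumerate(srow):
            if s is None:
                continue
            placed.setdefault(j - sign * s, {})[i] = row[j]
    cols = sorted(placed)
    rows = []
    for i in range(len(smap.names)):
        rows.append("".join(placed[c].get(i, "-") for c in cols))
    return AlnBlock(smap.names, tuple(rows))


def blocks_to_tsv(blocks: list[ShiftBlock], path) -> None:
    """Block table: shift, 1-based inclusive span, sequences, length."""
    with open(path, "w") as fh:
        fh.write("shift\tcol_start\tcol_end\tlength\tsequences\n")
        for b in blocks:
            fh.write(
                f"{b.shift}\t{b.col_span[0] + 1}\t{b.col_span[1]}\t{b.length}\t"
                + ",".join(sorted(b.rows)) + "\n"
            )
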