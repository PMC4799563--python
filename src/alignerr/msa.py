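"""Alignment data model, standard-format I/O, canonicalization and gap chopping.

The central object is :class:`Msa`, an ordered set of equal-length rows over
the DNA alphabet plus the gap character ``-``.  Aligners can only infer the
*homology structure* of an alignment — which residues sit in the same column —
not the left-to-right order of columns whose mutual order the sequences do not
constrain.  :func:`canonicalize` therefore maps every alignment with the same
homology structure to one byte-identical representative, which is what all
downstream comparisons operate on.

Columns are 0-based and half-open internally.  Shift-map output uses 1-based
positions; the conversion happens at the reporting boundary, not here.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import MsaFormatError

GAP = "-"
_ALPHABET = set("ACGTN-")


class _RowsApi:
    """Shared accessors for anything holding named, equal-length rows."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def ungapped(self) -> dict[str, str]:
        """Gap-free sequences keyed by name."""
        return {n: r.replace(GAP, "") for n, r in zip(self.names, self.rows)}

    def sub_msa(self, start: int, stop: int, drop_gap_only_rows: bool = False) -> "Msa":
        """Column slice [start, stop); rows that become all-gap are kept as-is
        unless ``drop_gap_only_rows`` (the Msa invariant forbids all-gap rows,
        so segment-level slices usually need the flag)."""
        names, rows = [], []
        for n, r in zip(self.names, self.rows):
            piece = r[start:stop]
            if drop_gap_only_rows and set(piece) <= {GAP}:
                continue
            names.append(n)
            rows.append(piece)
        return Msa(tuple(names), tuple(rows))

    # -- residue/column coordinate maps ------------------------------------

    def residue_columns(self) -> list[list[int]]:
        """For each row, the column index of each residue (by residue ordinal)."""
        out = []
        for r in self.rows:
            cols = [j for j, ch in enumerate(r) if ch != GAP]
            out.append(cols)
        return out

    def column_ordinals(self) -> list[list[int | None]]:
        """For each row, per column: the residue ordinal there, or None at gaps."""
        out = []
        for r in self.rows:
            ords: list[int | None] = []
            k = 0
            for ch in r:
                if ch == GAP:
                    ords.append(None)
                else:
                    ords.append(k)
                    k += 1
            out.append(ords)
        return out

    # -- I/O ---------------------------------------------------------------

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, r in zip(self.names, self.rows):
                fh.write(f">{n}\n{r}\n")


@dataclass(frozen=True)
class Msa(_RowsApi):
    """A multiple sequence alignment over {A,C,G,T,N,-}.

    ``names`` keeps input order; ``rows`` are uppercase strings of equal
    length.  ``N`` is treated as missing data by the likelihood machinery but
    as an ordinary residue (non-gap) by the gap segmentation.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if not self.rows:
            raise MsaFormatError("empty alignment")
        if len(self.names) != len(self.rows):
            raise MsaFormatError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise MsaFormatError("duplicate sequence names")
        n = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != n:
                raise MsaFormatError(
                    f"record {name!r} has length {len(row)}, expected {n}"
                )
            bad = set(row) - _ALPHABET
            if bad:
                raise MsaFormatError(f"record {name!r} has characters {sorted(bad)}")
            if set(row) == {GAP}:
                raise MsaFormatError(f"record {name!r} is all gaps")
        if n == 0:
            raise MsaFormatError("alignment has zero columns")


@dataclass(frozen=True)
class AlnBlock(_RowsApi):
    """A column slice of an alignment.

    Unlike :class:`Msa`, a block may contain rows that are entirely gaps
    (a sequence can simply have no residues inside a segment), so it skips
    the whole-alignment invariants.  It offers the same row accessors.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]


def read_alignment_fasta(path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Characters are upcased and U is mapped to T.  Records must have equal
    lengths; anything outside {A,C,G,T,U,N,-} is a format error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MsaFormatError(f"{path}: no FASTA records")
    names, rows = [], []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        names.append(rec.id)
        rows.append(seq)
    return Msa(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# Homology structure and canonicalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyStructure:
    """The order-free content of an alignment.

    Each column is the set of (row index, residue ordinal) pairs it
    homologizes.  Two alignments of the same sequences are equivalent exactly
    when these column sets coincide; the left-to-right order of columns is
    only partially constrained (within every row, ordinals must increase).
    """

    columns: tuple[frozenset[tuple[int, int]], ...]

    @property
    def key(self) -> frozenset[frozenset[tuple[int, int]]]:
        """Order-free equality key."""
        return frozenset(self.columns)


def homology_structure(msa: Msa) -> HomologyStructure:
    cols = []
    ords = msa.column_ordinals()
    for j in range(msa.n_cols):
        members = frozenset(
            (i, ords[i][j]) for i in range(msa.n_rows) if ords[i][j] is not None
        )
        if members:
            cols.append(members)
    return HomologyStructure(tuple(cols))


def same_homology(a: Msa, b: Msa) -> bool:
    """True when the two alignments homologize identically (names aligned by
    position: rows are matched by name, not index)."""
    if set(a.names) != set(b.names):
        return False
    if a.names != b.names:
        order = [b.names.index(n) for n in a.names]
        b = Msa(tuple(a.names), tuple(b.rows[i] for i in order))
    return homology_structure(a).key == homology_structure(b).key


def canonicalize(msa: Msa) -> Msa:
    """Return the canonical representative of ``msa``'s homology structure.

    All-gap columns are dropped.  The remaining columns form a partial order
    (within every row, residue ordinals must increase left to right); among
    columns whose mutual order is unconstrained, the one containing the
    residue of the lowest row index is emitted first, ties broken by the
    lowest residue ordinal.  A greedy topological sort with that priority is
    deterministic and depends only on the homology structure, so any two
    alignments with equal structure map to byte-identical output.
    """
    ords = msa.column_ordinals()
    n_rows, n_cols = msa.n_rows, msa.n_cols

    members: list[list[tuple[int, int]]] = []  # per kept column: (row, ordinal)
    keep: list[int] = []
    for j in range(n_cols):
        m = [(i, ords[i][j]) for i in range(n_rows) if ords[i][j] is not None]
        if m:
            keep.append(j)
            members.append(m)

    # Successor edges: consecutive residues of each row.
    idx_of = {}
    for cidx, m in enumerate(members):
        for i, r in m:
            idx_of[(i, r)] = cidx
    n = len(members)
    indeg = [0] * n
    succ: list[list[int]] = [[] for _ in range(n)]
    for cidx, m in enumerate(members):
        for i, r in m:
            nxt = idx_of.get((i, r + 1))
            if nxt is not None:
                succ[cidx].append(nxt)
                indeg[nxt] += 1

    def priority(cidx: int) -> tuple[int, int]:
        return min(members[cidx])

    heap = [(priority(c), c) for c in range(n) if indeg[c] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, c = heapq.heappop(heap)
        order.append(c)
        for nxt in succ[c]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                heapq.heappush(heap, (priority(nxt), nxt))
    if len(order) != n:  # pragma: no cover - impossible for a valid Msa
        raise MsaFormatError("cyclic homology constraints")

    residues = [[ch for ch in row if ch != GAP] for row in msa.rows]
    new_rows = [[GAP] * n for _ in range(n_rows)]
    for pos, cidx in enumerate(order):
        for i, r in members[cidx]:
            new_rows[i][pos] = residues[i][r]
    return Msa(msa.names, tuple("".join(r) for r in new_rows))


def is_canonical(msa: Msa) -> bool:
    return canonicalize(msa).rows == msa.rows


# ---------------------------------------------------------------------------
# Gap segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapSegmentation:
    """Alternating gapless/gapped column spans tiling [0, n_cols).

    A gapped span is a maximal run of columns each containing at least one
    gap; adjacent gap-containing columns always fuse into one segment.
    """

    spans: tuple[tuple[int, int, str], ...]  # (start, stop, "gapless"|"gapped")

    def __iter__(self) -> Iterator[tuple[int, int, str]]:
        return iter(self.spans)

    @property
    def gapped_spans(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab in self.spans if lab == "gapped"]

    @property
    def gapless_spans(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab in self.spans if lab == "gapless"]

    @property
    def n_gapped(self) -> int:
        return len(self.gapped_spans)

    def gapped_lengths(self) -> list[int]:
        return [b - a for a, b in self.gapped_spans]

    def gapless_lengths(self) -> list[int]:
        return [b - a for a, b in self.gapless_spans]

    def to_tsv(self, path, name: str = "msa") -> None:
        """BED-like TSV: name, start, end, label (0-based half-open)."""
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\tlabel\n")
            for a, b, lab in self.spans:
                fh.write(f"{name}\t{a}\t{b}\t{lab}\n")


def gap_segmentation(msa: Msa) -> GapSegmentation:
    """Chop ``msa`` into maximal alternating gapless and gapped column spans."""
    has_gap = [GAP in msa.column(j) for j in range(msa.n_cols)]
    spans = []
    start = 0
    for j in range(1, msa.n_cols + 1):
        if j == msa.n_cols or has_gap[j] != has_gap[start]:
            spans.append((start, j, "gapped" if has_gap[start] else "gapless"))
            start = j
    return GapSegmentation(tuple(spans))


def apparent_indel_runs(
    msa: Msa, span: tuple[int, int] | None = None
) -> list[tuple[str, int, int]]:
    """Maximal single-row gap runs intersecting ``span``.

    Returns (sequence name, run start column, full run length) for every
    maximal run of ``-`` in one row that overlaps the column interval; the
    full length is reported even where the run extends past the interval.
    """
    lo, hi = (0, msa.n_cols) if span is None else span
    if not (0 <= lo <= hi <= msa.n_cols):
        raise ValueError(f"span {span} out of bounds for {msa.n_cols} columns")
    out = []
    for name, row in zip(msa.names, msa.rows):
        j = 0
        n = len(row)
        while j < n:
            if row[j] == GAP:
                k = j
                while k < n and row[k] == GAP:
                    k += 1
                if j < hi and k > lo:  # run [j, k) intersects [lo, hi)
                    out.append((name, j, k - j))
                j = k
            else:
                j += 1
    return out


def has_long_indel(msa: Msa, span: tuple[int, int] | None = None, threshold: int = 100) -> bool:
    """True iff some apparent indel run intersecting ``span`` is strictly
    longer than ``threshold`` columns ("over 100 bases long")."""
    return any(length > threshold for _, _, length in apparent_indel_runs(msa, span))
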