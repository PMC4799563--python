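"""Inject single, labeled alignment errors into a true MSA.

Each injector rewrites one column window of a canonical true alignment so
that the result is an alignment of the *same* sequences whose homology
structure differs from the truth by exactly one named error (or one
intrinsically paired error).  The returned reconstruction carries its
ground-truth label, which is what the error classifier is validated against.

Supported types and their constructions (S, S1, S2 denote clades that are
not children of the root, so the parsimonious event inference is clean):

* ``shift``              — move a single clade-absence gap k columns left.
* ``merge_same_type``    — two same-clade gaps with a short gapless stretch
                            between them become one combined gap.
* ``split``              — one clade gap becomes two, separated by residues
                            pulled across from the right flank.
* ``merge_opposite_type``— a clade insertion-gap and deletion-gap of unequal
                            size nearby collapse into one residual gap.
* ``purge``              — same with equal sizes: both gaps vanish.
* ``ex_nihilo``          — a gapless region acquires a spurious equal-size
                            deletion-gap/insertion-gap pair (reverse purge).
* ``CII``                — equal-length insertions in sibling clades at the
                            same ancestral position aligned as one insertion
                            on the parent branch.
* ``iCII``               — same with unequal lengths: partial collapse with
                            a residual sibling insertion.
* ``CSII``               — one parent-branch insertion split into spurious
                            independent sibling insertions (reverse CII).
* ``iCSII``              — an adjacent sibling-insertion + parent-insertion
                            pair un-collapsed into independent insertions
                            (reverse iCII).

``v_merge``/``v_split`` are not injectable: inside an anchored erroneous
segment, residue conservation forces the residues of (parent clade minus
child clade) to reappear as a residual run, so the bare two-deletions-to-one
signature cannot be realized by any alignment of the same sequences; the
classifier still recognizes the pattern when real data truncate it into
view.  Requesting them raises :class:`CapabilityError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, DomainError
from .histories import pattern_runs
from .msa import AlnBlock, GAP, Msa, canonicalize, gap_segmentation
from .phylo import PhyloTree

INJECTABLE_TYPES = (
    "shift", "merge_same_type", "split", "merge_opposite_type", "purge",
    "ex_nihilo", "CII", "iCII", "CSII", "iCSII",
)


@dataclass(frozen=True)
class InjectionTarget:
    """A concrete place where one error type can be injected."""

    type: str
    window: tuple[int, int]  # true columns to rewrite
    params: tuple  # type-specific, hashable


@dataclass(frozen=True)
class InjectionResult:
    rec: Msa
    label: str
    target: InjectionTarget


# ---------------------------------------------------------------------------
# Target discovery
# ---------------------------------------------------------------------------

def _span_info(msa: Msa, tree: PhyloTree):
    """Per gapped span: (span, runs, left gapless width, right gapless width)."""
    seg = gap_segmentation(msa)
    spans = list(seg.spans)
    out = []
    for i, (a, b, lab) in enumerate(spans):
        if lab != "gapped":
            continue
        left = spans[i - 1][1] - spans[i - 1][0] if i > 0 else 0
        right = spans[i + 1][1] - spans[i + 1][0] if i + 1 < len(spans) else 0
        block = AlnBlock(msa.names, tuple(r[a:b] for r in msa.rows))
        out.append(((a, b), pattern_runs(block, tree), left, right))
    return out


def _clade_tables(tree: PhyloTree):
    mask_to_node = {}
    for n in tree.branches():
        mask_to_node[tree.mask(n)] = n
    return mask_to_node


def _eligible(tree: PhyloTree, mask_to_node, mask: int):
    """The node of a clade mask, provided it is not a child of the root."""
    node = mask_to_node.get(mask)
    if node is None or tree.parent[node] == 0:
        return None
    return node


def _pair_span_targets(infos, tree, m2n, full, error_type, max_mid, targets):
    """Neighboring single-run gapped spans with a short gapless stretch in
    between: same-pattern pairs feed merge_same_type, clade insertion-gap /
    deletion-gap pairs feed merge_opposite_type and purge."""
    for i in range(len(infos) - 1):
        (a1, b1), runs1, _, _ = infos[i]
        (a2, b2), runs2, _, _ = infos[i + 1]
        if len(runs1) != 1 or len(runs2) != 1:
            continue
        mid = a2 - b1
        if mid < 1 or mid > max_mid:
            continue
        m1, m2 = runs1[0][0], runs2[0][0]
        g1, g2 = b1 - a1, b2 - a2
        if error_type == "merge_same_type":
            if m1 == m2 and _eligible(tree, m2n, full & ~m1) is not None:
                targets.append(
                    InjectionTarget("merge_same_type", (a1, b2), (g1, g2, mid))
                )
        else:
            for first_is_ins in (True, False):
                pm, dm = (m1, m2) if first_is_ins else (m2, m1)
                node = _eligible(tree, m2n, pm)
                if node is None or dm != (full & ~pm):
                    continue
                gi, gd = (g1, g2) if first_is_ins else (g2, g1)
                if (gi == gd) == (error_type == "purge"):
                    targets.append(
                        InjectionTarget(
                            error_type, (a1, b2), (first_is_ins, gi, gd, mid)
                        )
                    )


def prepare_injection_info(msa: Msa, tree: PhyloTree):
    """Precompute the span/clade tables shared by all target searches."""
    return _span_info(msa, tree), _clade_tables(tree)


def find_targets(msa: Msa, tree: PhyloTree, error_type: str,
                 max_mid: int = 8, max_shift: int = 6,
                 info=None) -> list[InjectionTarget]:
    """All positions in ``msa`` supporting one injection of ``error_type``."""
    if error_type in ("v_merge", "v_split"):
        raise CapabilityError(
            f"{error_type} cannot be realized as a single-segment injection"
        )
    if error_type not in INJECTABLE_TYPES:
        raise CapabilityError(f"unknown error type {error_type!r}")
    full = tree.all_leaves_mask
    infos, m2n = prepare_injection_info(msa, tree) if info is None else info
    targets = []

    def absence_clade(mask):
        return _eligible(tree, m2n, full & ~mask)

    def presence_clade(mask):
        return _eligible(tree, m2n, mask)

    if error_type == "shift":
        for (a, b), runs, left, right in infos:
            if len(runs) != 1:
                continue
            if absence_clade(runs[0][0]) is None:
                continue
            k = min(max_shift, left - 1)
            if k >= 1:
                targets.append(InjectionTarget("shift", (a - k, b), (k,)))

    elif error_type == "split":
        for (a, b), runs, left, right in infos:
            if len(runs) != 1 or (b - a) < 2:
                continue
            if absence_clade(runs[0][0]) is None:
                continue
            m = min(3, right - 1)
            if m >= 1:
                l1 = (b - a) // 2
                targets.append(
                    InjectionTarget("split", (a, b + m), (l1, m, "right")))

    elif error_type in ("merge_opposite_type", "purge"):
        # within-span form: one gapped span whose two runs are a clade
        # insertion-gap directly against the matching deletion-gap
        for (a, b), runs, _, _ in infos:
            if len(runs) != 2:
                continue
            (m1, (c1, d1)), (m2, (c2, d2)) = runs
            g1, g2 = d1 - c1, d2 - c2
            for first_is_ins in (True, False):
                pm, dm = (m1, m2) if first_is_ins else (m2, m1)
                node = _eligible(tree, m2n, pm)
                if node is None or dm != (full & ~pm):
                    continue
                gi, gd = (g1, g2) if first_is_ins else (g2, g1)
                if (gi == gd) == (error_type == "purge"):
                    targets.append(
                        InjectionTarget(error_type, (a, b), (first_is_ins, gi, gd, 0))
                    )
        _pair_span_targets(infos, tree, m2n, full, error_type, max_mid, targets)

    elif error_type == "merge_same_type":
        _pair_span_targets(infos, tree, m2n, full, error_type, max_mid, targets)

    elif error_type == "ex_nihilo":
        seg = gap_segmentation(msa)
        for a, b, lab in seg.spans:
            if lab != "gapless" or (b - a) < 8:
                continue
            g, c, mid = 2, 2, 2
            d = c + g + mid
            if d + g > (b - a) - 1:
                continue
            for node in tree.branches():
                if tree.parent[node] == 0:
                    continue
                targets.append(
                    InjectionTarget("ex_nihilo", (a, b), (tree.mask(node), c, d, g))
                )
        return targets

    elif error_type in ("CII", "iCII"):
        # clean collapses need the sibling pair to be the whole gapped span
        for (a, b), runs, _, _ in infos:
            if len(runs) != 2:
                continue
            (mask1, (c1, d1)), (mask2, (c2, d2)) = runs
            n1 = presence_clade(mask1)
            n2 = presence_clade(mask2)
            if n1 is None or n2 is None:
                continue
            par = tree.parent[n1]
            if par != tree.parent[n2] or len(tree.children[par]) != 2:
                continue
            if _eligible(tree, m2n, tree.mask(par)) is None:
                continue
            g1, g2 = d1 - c1, d2 - c2
            equal = g1 == g2
            if equal == (error_type == "CII"):
                targets.append(
                    InjectionTarget(error_type, (a + c1, a + d2), (g1, g2, mask1, mask2))
                )

    elif error_type == "CSII":
        for (a, b), runs, _, _ in infos:
            if len(runs) != 1:
                continue
            node = presence_clade(runs[0][0])
            if node is None or len(tree.children[node]) != 2:
                continue
            ch = tree.children[node]
            targets.append(
                InjectionTarget("CSII", (a, b), (tree.mask(ch[0]), tree.mask(ch[1])))
            )

    elif error_type == "iCSII":
        for (a, b), runs, _, _ in infos:
            if len(runs) != 2:
                continue
            (mask1, (c1, d1)), (mask2, (c2, d2)) = runs
            n1 = presence_clade(mask1)
            nP = presence_clade(mask2)
            if n1 is None or nP is None or tree.parent[n1] != nP:
                continue
            sibs = [c for c in tree.children[nP] if c != n1]
            if len(sibs) != 1:
                continue
            targets.append(
                InjectionTarget(
                    "iCSII", (a + c1, a + d2),
                    (d1 - c1, d2 - c2, mask1, tree.mask(sibs[0])),
                )
            )
    return targets


# ---------------------------------------------------------------------------
# Window surgery
# ---------------------------------------------------------------------------

def _rewrite(msa: Msa, window, new_rows_fn) -> Msa:
    """Replace columns [a, b) using new_rows_fn(row_index, old_piece)."""
    a, b = window
    rows = []
    for i, r in enumerate(msa.rows):
        piece = new_rows_fn(i, r[a:b])
        rows.append(r[:a] + piece + r[b:])
    rec = Msa(msa.names, tuple(rows))
    if rec.ungapped() != msa.ungapped():
        raise AssertionError("injection altered residue content")
    return canonicalize(rec)


def _in_mask(msa: Msa, tree: PhyloTree, mask: int):
    return [bool(mask >> tree.leaf_bit(n) & 1) for n in msa.names]


def inject_elementary_error(msa: Msa, tree: PhyloTree,
                            target: InjectionTarget | dict,
                            rng: np.random.Generator | None = None) -> InjectionResult:
    """Apply one labeled error at ``target``.

    ``target`` may be an :class:`InjectionTarget` from :func:`find_targets`
    or a dict ``{"type": ..., ...}`` in which case a supporting target is
    searched (``rng`` picks among candidates, else the first is used).
    """
    if isinstance(target, dict):
        cands = find_targets(msa, tree, target["type"])
        if not cands:
            raise CapabilityError(
                f"no target in this MSA supports {target['type']!r}"
            )
        if rng is not None:
            target = cands[int(rng.integers(len(cands)))]
        else:
            target = cands[0]

    t = target.type
    a, b = target.window
    full = tree.all_leaves_mask

    if t == "shift":
        (k,) = target.params
        # window = [gap span shifted left by k]; rows absent in the span's
        # pattern move their k flank residues to the right of the gap
        block = AlnBlock(msa.names, tuple(r[a + k:b] for r in msa.rows))
        mask = pattern_runs(block, tree)[0][0]
        in_p = _in_mask(msa, tree, mask)

        def fn(i, piece):
            if in_p[i]:
                return piece
            return piece[k:] + piece[:k]  # gaps first, then the residues

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "merge_same_type":
        g1, g2, mid = target.params
        block = AlnBlock(msa.names, tuple(r[a:a + g1] for r in msa.rows))
        mask = pattern_runs(block, tree)[0][0]
        in_p = _in_mask(msa, tree, mask)

        def fn(i, piece):
            if in_p[i]:
                return piece
            return piece[g1:g1 + mid] + GAP * (g1 + g2)

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "split":
        l1, m, side = (*target.params, "right")[:3]
        g = (b - a) - m
        # the gap sits left of the window's flank residues for side="right",
        # right of them for side="left"
        gap_lo = a if side == "right" else a + m
        block = AlnBlock(msa.names, tuple(r[gap_lo:gap_lo + g] for r in msa.rows))
        mask = pattern_runs(block, tree)[0][0]
        in_p = _in_mask(msa, tree, mask)

        def fn(i, piece):
            if in_p[i]:
                return piece
            res = piece.replace(GAP, "")
            return GAP * l1 + res + GAP * (g - l1)

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t in ("merge_opposite_type", "purge"):
        _, gi, gd, mid = target.params
        # start-align every row's residues; the longer side's tail becomes
        # the single residual gap run (none when the sizes are equal)
        width = max(gi, gd) + mid

        def fn(i, piece):
            res = piece.replace(GAP, "")
            return res + GAP * (width - len(res))

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "ex_nihilo":
        s_mask, c, d, g = target.params
        in_s = _in_mask(msa, tree, s_mask)

        def fn(i, piece):
            if in_s[i]:
                return piece[:c] + GAP * g + piece[c:]
            return piece[:d] + GAP * g + piece[d:]

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "CII":
        g1, g2, mask1, mask2 = target.params
        in_1 = _in_mask(msa, tree, mask1)
        in_2 = _in_mask(msa, tree, mask2)

        def fn(i, piece):
            if in_1[i]:
                return piece[:g1]
            if in_2[i]:
                return piece[g1:]
            return GAP * g1

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "iCII":
        g1, g2, mask1, mask2 = target.params
        in_1 = _in_mask(msa, tree, mask1)
        in_2 = _in_mask(msa, tree, mask2)
        gmin = min(g1, g2)

        def fn(i, piece):
            if in_1[i]:
                return piece[:g1] + GAP * (g2 - gmin)
            if in_2[i]:
                return GAP * (max(g1, g2) - g2) + piece[g1:]
            return GAP * max(g1, g2)

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "CSII":
        mask1, mask2 = target.params
        g = b - a
        in_1 = _in_mask(msa, tree, mask1)
        in_2 = _in_mask(msa, tree, mask2)

        def fn(i, piece):
            if in_1[i]:
                return piece + GAP * g
            if in_2[i]:
                return GAP * g + piece
            return GAP * (2 * g)

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    if t == "iCSII":
        ga, gb, mask1, mask_sib = target.params
        in_1 = _in_mask(msa, tree, mask1)
        in_sib = _in_mask(msa, tree, mask_sib)

        def fn(i, piece):
            if in_1[i]:
                return piece.replace(GAP, "") + GAP * gb
            if in_sib[i]:
                return GAP * (ga + gb) + piece[ga:].replace(GAP, "")
            return GAP * (ga + 2 * gb)

        return InjectionResult(_rewrite(msa, (a, b), fn), t, target)

    raise CapabilityError(f"unknown or unsupported error type {t!r}")
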