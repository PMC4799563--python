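"""Parsimonious indel histories of gapped segments, weights and counts.

A gapped segment (maximal run of gap-containing columns flanked by gapless
ones) shows, for each column, which leaves carry a residue.  An *indel
history* explains that presence/absence matrix with insertion and deletion
events on tree branches; a *parsimonious* history uses the minimum number of
events.  All parsimonious histories are enumerated, weighted by a
leading-order continuous-time probability factor per event, and the weighted
ensemble drives both the indel component of the complete-likelihood score
and the probability-weighted insertion/deletion counts whose true-vs-
reconstructed differences are the misestimation measures.

Events are resolved at the granularity of maximal column runs with an
identical presence pattern; one event may cover several runs when the runs
in between are absent from the event's lineage at the time it fires (that is
what makes two gaps "adjacent" in a sequence even if the alignment shows
other material between them).  Variants that split a run into two same-branch
events are never count-parsimonious and are not generated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import DomainError, IntractableSegmentError
from .phylo import PhyloTree
from .sim import IndelModel

MAX_HISTORIES = 10_000
MAX_EVENTS = 12
_MAX_ASSIGNMENTS = 200_000
_MAX_WORK = 2_000_000  # search-node budget; beyond it a segment is intractable


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelEvent:
    """One inferred event: ``runs`` are the covered pattern-run indices.

    ``span`` is the column interval from the first to the last covered
    column (segment-local); ``length`` is the number of residues actually
    inserted/deleted, i.e. the summed length of the covered runs (the span is
    wider when the event skips runs absent from its lineage).
    """

    kind: str  # "insertion" | "deletion"
    branch: int  # node id below the branch
    runs: tuple[int, ...]
    span: tuple[int, int]
    length: int


@dataclass(frozen=True)
class IndelHistory:
    """A set of events jointly explaining one gapped segment."""

    events: tuple[IndelEvent, ...]  # sorted, canonical

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_insertions(self) -> int:
        return sum(1 for e in self.events if e.kind == "insertion")

    @property
    def n_deletions(self) -> int:
        return sum(1 for e in self.events if e.kind == "deletion")

    def sort_key(self):
        return tuple((e.kind, e.branch, e.runs) for e in self.events)


@dataclass
class HistoryEnsemble:
    """All parsimonious histories of a segment with their weights."""

    histories: list[IndelHistory]
    weights: list[float]
    runs: tuple  # (pattern mask, (col0, col1)) per run
    capped: bool = False

    @property
    def normalization(self) -> float:
        """Segment contribution to the indel probability (before the overall
        factor): the sum of history weights."""
        return float(sum(self.weights))

    def representative(self) -> IndelHistory:
        """Max-weight history; ties prefer fewer insertions, then the
        lexicographically first event set."""
        best = None
        key = None
        for h, w in zip(self.histories, self.weights):
            k = (-w, h.n_insertions, h.sort_key())
            if key is None or k < key:
                best, key = h, k
        if best is None:
            raise DomainError("empty ensemble has no representative")
        return best


@dataclass(frozen=True)
class IndelCounts:
    """Probability-weighted expected numbers of insertions and deletions."""

    insertions: float
    deletions: float


@dataclass(frozen=True)
class Misestimation:
    """The three indel-count misestimation measures (reconstructed - true).

    ordinary_difference = [del_R - del_T] + [ins_R - ins_T]
    l1_distance         = |del_R - del_T| + |ins_R - ins_T|
    deletion_bias       = [del_R - del_T] - [ins_R - ins_T]
    """

    ordinary_difference: float
    l1_distance: float
    deletion_bias: float


# ---------------------------------------------------------------------------
# Pattern runs
# ---------------------------------------------------------------------------

def pattern_runs(block, tree: PhyloTree):
    """Maximal column runs with identical presence pattern.

    Returns a tuple of (presence bitmask over tree.leaf_names, (start, stop))
    pairs; every column must contain at least one gap and one residue.
    """
    bits = [tree.leaf_bit(n) for n in block.names]
    full = 0
    for b in bits:
        full |= 1 << b
    runs = []
    prev = None
    start = 0
    n_cols = len(block.rows[0]) if block.rows else 0
    for j in range(n_cols):
        mask = 0
        for i, row in enumerate(block.rows):
            if row[j] != "-":
                mask |= 1 << bits[i]
        if mask == 0 or mask == full:
            raise DomainError(
                "gapped-segment columns must mix residues and gaps"
            )
        if mask != prev:
            if prev is not None:
                runs.append((prev, (start, j)))
            prev, start = mask, j
    if prev is not None:
        runs.append((prev, (start, n_cols)))
    return tuple(runs)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _subtree_covers(tree: PhyloTree, mask: int, cap: int):
    """All ways to write ``mask`` as a disjoint union of subtree clades.

    The maximal subtrees contained in ``mask`` always tile it (leaves are
    subtrees); each may stay whole or be split recursively into children.
    """
    if mask == 0:
        return [()]

    def maximal(node: int, m: int):
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            nm = tree.mask(n)
            if nm & m == nm and n != 0:
                out.append(n)
            else:
                stack.extend(tree.children[n])
        return out

    def expand(node: int):
        # covers of exactly mask(node)
        res = [(node,)]
        if tree.children[node]:
            child_cov = [expand(c) for c in tree.children[node]]
            for combo in itertools.product(*child_cov):
                res.append(tuple(x for part in combo for x in part))
                if len(res) > cap:
                    raise IntractableSegmentError("deletion cover cap exceeded")
        return res

    tops = maximal(0, mask)
    parts = [expand(t) for t in tops]
    covers = []
    for combo in itertools.product(*parts):
        covers.append(tuple(sorted(x for part in combo for x in part)))
        if len(covers) > cap:
            raise IntractableSegmentError("deletion cover cap exceeded")
    return covers


def _run_options(tree: PhyloTree, pattern: int, cap: int):
    """Per-run fate options: (creation branch or None for root ancestry,
    tuple of deletion branches)."""
    leaves = [i for i in tree.leaf_ids() if tree.mask(i) & pattern]
    mrca = tree.mrca_node(leaves)
    chain = []
    node = mrca
    while node is not None:
        chain.append(node)
        node = tree.parent[node]
    options = []
    full = tree.all_leaves_mask
    for creation in chain:
        scope = tree.mask(creation)
        absent = scope & ~pattern
        for cover in _subtree_covers(tree, absent, cap):
            if creation == 0:
                options.append((None, cover))
            else:
                # an insertion's deletions must fall strictly below it
                if all(tree.is_ancestor(creation, d) and d != creation for d in cover):
                    options.append((creation, cover))
    return options


def _branch_order_ok(events, state_in: frozenset, branch: int):
    """Is there an order of ``events`` on one branch that respects presence
    and lineage-contiguity?  Returns the final state or None."""
    final = set(state_in)
    for e in events:
        if e.kind == "deletion":
            final.difference_update(e.runs)
        else:
            final.update(e.runs)
    for order in itertools.permutations(events):
        state = set(state_in)
        ok = True
        for e in order:
            lo, hi = min(e.runs), max(e.runs)
            if e.kind == "deletion":
                if not set(e.runs) <= state:
                    ok = False
                    break
                if any(k in state and k not in e.runs for k in range(lo, hi + 1)):
                    ok = False
                    break
                state.difference_update(e.runs)
            else:
                if set(e.runs) & state:
                    ok = False
                    break
                if any(k in state and k not in e.runs for k in range(lo, hi + 1)):
                    ok = False
                    break
                state.update(e.runs)
        if ok:
            return frozenset(final)
    return None


def _history_valid(events, runs, tree: PhyloTree) -> bool:
    """Replay a candidate event set down the tree.

    Checks per-branch orderability and that every leaf ends up with exactly
    the runs whose pattern contains it.
    """
    by_branch: dict[int, list[IndelEvent]] = {}
    for e in events:
        by_branch.setdefault(e.branch, []).append(e)

    root_state = frozenset(
        k for k, _ in enumerate(runs)
        if not any(e.kind == "insertion" and k in e.runs for e in events)
    )

    def down(node: int, state: frozenset) -> bool:
        if node != 0:
            evs = by_branch.get(node, [])
            if evs:
                state = _branch_order_ok(evs, state, node)
                if state is None:
                    return False
        if tree.is_leaf(node):
            bit = 1 << tree.leaf_bit(tree.label[node])
            want = frozenset(k for k, (mask, _) in enumerate(runs) if mask & bit)
            return state == want
        return all(down(c, state) for c in tree.children[node])

    return down(0, root_state)


def _set_partitions(items):
    """All partitions of a small list into non-empty groups."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def enumerate_parsimonious_histories(
    block, tree: PhyloTree,
    max_histories: int = MAX_HISTORIES,
    max_events: int = MAX_EVENTS,
) -> HistoryEnsemble:
    """Enumerate every minimum-event history explaining one gapped segment.

    ``block`` holds the segment's columns (each with at least one gap and one
    residue); a gapless block yields the single empty history with weight 1.
    Raises :class:`IntractableSegmentError` (with the partial ensemble, if
    any) when the caps are exceeded.
    """
    n_cols = len(block.rows[0]) if block.rows else 0
    if n_cols == 0 or all("-" not in r for r in block.rows):
        ens = HistoryEnsemble([IndelHistory(())], [1.0], ())
        return ens

    runs = pattern_runs(block, tree)
    m = len(runs)
    options = [_run_options(tree, mask, cap=max_histories) for mask, _ in runs]
    # cheapest fates first so a good bound is found immediately
    options = [
        sorted(opts, key=lambda o: (o[0] is not None) + len(o[1]))
        for opts in options
    ]

    best_count: int | None = None
    found: dict[tuple, IndelHistory] = {}
    explored = 0

    def consider(events: list) -> None:
        """Fold one candidate event set into ``found`` if minimal & valid."""
        nonlocal best_count, found
        count = len(events)
        if count > max_events:
            return
        if best_count is not None and count > best_count:
            return
        events = tuple(sorted(events, key=lambda e: (e.kind, e.branch, e.runs)))
        key = tuple((e.kind, e.branch, e.runs) for e in events)
        if key in found:
            return
        if not _history_valid(events, runs, tree):
            return
        if best_count is None or count < best_count:
            best_count = count
            found = {key: IndelHistory(events)}
        elif count == best_count:
            found[key] = IndelHistory(events)
            if len(found) > max_histories:
                raise IntractableSegmentError(
                    f"more than {max_histories} parsimonious histories",
                    partial=HistoryEnsemble(list(found.values()),
                                            [1.0] * len(found), runs,
                                            capped=True),
                )

    def group_partitions(ks: list):
        """Partitions of one group's runs into candidate events, ordered by
        part count.  Small groups are partitioned exhaustively; large
        same-branch groups use consecutive-interval partitions only (a
        non-consecutive merged event needs an interleaved same-branch event
        ordered before it, which interval splits almost always cover)."""
        if len(ks) <= 6:
            parts = list(_set_partitions(ks))
        elif len(ks) <= 14:
            n = len(ks)
            parts = []
            for cuts in range(1 << (n - 1)):
                p, cur = [], [ks[0]]
                for i in range(1, n):
                    if cuts >> (i - 1) & 1:
                        p.append(cur)
                        cur = [ks[i]]
                    else:
                        cur.append(ks[i])
                p.append(cur)
                parts.append(p)
        else:
            raise IntractableSegmentError(
                f"{len(ks)} same-branch atoms exceed the merge cap",
                partial=None)
        parts.sort(key=len)
        return parts

    def evaluate(assignment) -> None:
        """Merge-partition the assignment's atoms into event sets and fold
        minimal ones into ``found``."""
        groups: dict[tuple, list[int]] = {}
        for k, (creation, cover) in enumerate(assignment):
            if creation is not None:
                groups.setdefault(("insertion", creation), []).append(k)
            for d in cover:
                groups.setdefault(("deletion", d), []).append(k)
        group_items = [
            (kind, branch, group_partitions(ks))
            for (kind, branch), ks in groups.items()
        ]

        def rec(idx: int, events: list) -> None:
            work[0] += 1
            if work[0] > _MAX_WORK:
                raise IntractableSegmentError(
                    "enumeration work cap exceeded",
                    partial=HistoryEnsemble(list(found.values()),
                                            [1.0] * len(found), runs,
                                            capped=True) if found else None,
                )
            if best_count is not None and \
                    len(events) + (len(group_items) - idx) > best_count:
                return
            if idx == len(group_items):
                consider(list(events))
                return
            kind, branch, parts = group_items[idx]
            for part in parts:
                if best_count is not None and \
                        len(events) + len(part) > best_count:
                    break  # parts are ordered by size
                evts = list(events)
                for grp in part:
                    grp = tuple(sorted(grp))
                    span = (runs[grp[0]][1][0], runs[grp[-1]][1][1])
                    length = sum(runs[k][1][1] - runs[k][1][0] for k in grp)
                    evts.append(IndelEvent(kind, branch, grp, span, length))
                rec(idx + 1, evts)

        rec(0, [])

    def dfs(k: int, partial, groups: set) -> None:
        """Depth-first over per-run fates; a joint assignment can never use
        fewer events than its number of distinct (kind, branch) groups, so
        subtrees exceeding the best known count are pruned."""
        nonlocal explored
        work[0] += 1
        if work[0] > _MAX_WORK:
            raise IntractableSegmentError(
                "enumeration work cap exceeded",
                partial=HistoryEnsemble(list(found.values()),
                                        [1.0] * len(found), runs,
                                        capped=True) if found else None,
            )
        if best_count is not None and len(groups) > best_count:
            return
        if k == m:
            explored += 1
            if explored > _MAX_ASSIGNMENTS:
                raise IntractableSegmentError(
                    f"assignment space exceeds {_MAX_ASSIGNMENTS}",
                    partial=HistoryEnsemble(list(found.values()),
                                            [1.0] * len(found), runs,
                                            capped=True) if found else None,
                )
            evaluate(partial)
            return
        for creation, cover in options[k]:
            added = set()
            if creation is not None:
                added.add(("insertion", creation))
            for d in cover:
                added.add(("deletion", d))
            dfs(k + 1, partial + [(creation, cover)], groups | added)

    work = [0]
    dfs(0, [], set())

    if best_count is None:
        raise IntractableSegmentError("no valid history within caps", partial=None)
    if best_count > max_events:
        raise IntractableSegmentError(
            f"minimal history needs more than {max_events} events", partial=None
        )
    histories = sorted(found.values(), key=lambda h: h.sort_key())
    return HistoryEnsemble(histories, [1.0] * len(histories), runs)


# ---------------------------------------------------------------------------
# Weights, counts, misestimation
# ---------------------------------------------------------------------------

def history_weight(h: IndelHistory, model: IndelModel, tree: PhyloTree) -> float:
    """Leading-order probability factor of a history.

    Product over events of rate(kind) * f(length) * branch length, with a
    1/k! factor per branch carrying k events (unordered same-branch events).
    Exit-rate exponentials live in the MSA-level overall factor instead (they
    cancel in the score comparisons these weights feed).  Events on
    zero-length branches, or longer than the length cutoff, are impossible
    (weight 0).
    """
    w = 1.0
    per_branch: dict[int, int] = {}
    law = model.length
    for e in h.events:
        t = tree.length[e.branch]
        if t <= 0.0:
            return 0.0
        if law.cutoff is not None and e.length > law.cutoff:
            return 0.0
        rate = model.ins_rate if e.kind == "insertion" else model.del_rate
        w *= rate * float(law.pmf(e.length)) * t
        per_branch[e.branch] = per_branch.get(e.branch, 0) + 1
    for k in per_branch.values():
        for i in range(2, k + 1):
            w /= i
    return w


def weight_ensemble(ens: HistoryEnsemble, model: IndelModel,
                    tree: PhyloTree) -> HistoryEnsemble:
    """Attach model weights to an enumerated ensemble (dropping impossible
    zero-weight histories unless all weights vanish)."""
    ws = [history_weight(h, model, tree) for h in ens.histories]
    if any(w > 0 for w in ws):
        pairs = [(h, w) for h, w in zip(ens.histories, ws) if w > 0]
        hs = [h for h, _ in pairs]
        ws = [w for _, w in pairs]
    else:
        hs = ens.histories
    return HistoryEnsemble(hs, ws, ens.runs, capped=ens.capped)


def expected_indel_counts(ens: HistoryEnsemble) -> IndelCounts:
    """Probability-weighted average insertion and deletion counts."""
    z = ens.normalization
    if not ens.histories:
        raise DomainError("empty ensemble")
    if z <= 0:
        # all histories impossible under the model: counts undefined; report
        # the unweighted average to stay total
        n = len(ens.histories)
        return IndelCounts(
            sum(h.n_insertions for h in ens.histories) / n,
            sum(h.n_deletions for h in ens.histories) / n,
        )
    ins = sum(w * h.n_insertions for h, w in zip(ens.histories, ens.weights)) / z
    dels = sum(w * h.n_deletions for h, w in zip(ens.histories, ens.weights)) / z
    return IndelCounts(ins, dels)


def misestimation_measures(true_counts: IndelCounts,
                           rec_counts: IndelCounts) -> Misestimation:
    """The three misestimation measures between reconstructed and true."""
    d_del = rec_counts.deletions - true_counts.deletions
    d_ins = rec_counts.insertions - true_counts.insertions
    return Misestimation(
        ordinary_difference=d_del + d_ins,
        l1_distance=abs(d_del) + abs(d_ins),
        deletion_bias=d_del - d_ins,
    )


def add_counts(a: IndelCounts, b: IndelCounts) -> IndelCounts:
    return IndelCounts(a.insertions + b.insertions, a.deletions + b.deletions)


def ensemble_to_tsv(ens: HistoryEnsemble, path, segment_id="segment") -> None:
    """Dump an ensemble: one row per history with its weight and events
    (kind:branch:runs:length, ';'-separated)."""
    with open(path, "w") as fh:
        fh.write("segment\thistory\tweight\tevents\n")
        for i, (h, w) in enumerate(zip(ens.histories, ens.weights)):
            evs = ";".join(
                f"{e.kind}:{e.branch}:{','.join(map(str, e.runs))}:{e.length}"
                for e in h.events
            )
            fh.write(f"{segment_id}\t{i}\t{w:.6g}\t{evs}\n")
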