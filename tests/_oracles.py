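"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by exhaustive search with their own
replay logic, sharing no code with the package's algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np

from alignerr.msa import GAP
from alignerr.phylo import PhyloTree


# ---------------------------------------------------------------------------
# Exhaustive parsimonious-history search
# ---------------------------------------------------------------------------

def block_patterns(block, tree: PhyloTree):
    """(mask, n_cols) pattern runs, computed straightforwardly."""
    bits = {n: tree.leaf_bit(n) for n in block.names}
    masks = []
    for j in range(len(block.rows[0])):
        m = 0
        for name, row in zip(block.names, block.rows):
            if row[j] != GAP:
                m |= 1 << bits[name]
        masks.append(m)
    runs = []
    for m, grp in itertools.groupby(masks):
        runs.append((m, len(list(grp))))
    return runs


def _replays(events, patterns, tree: PhyloTree) -> bool:
    """Naive recursive replay of an event set (kind, branch, runs-frozenset).

    Presence states are sets of run indices; per-branch event order is
    searched exhaustively; an event must act on a set of runs forming a
    contiguous stretch of the runs present in its lineage at firing time.
    """
    m = len(patterns)
    created_by: dict[int, int] = {}
    for idx, (kind, b, rs) in enumerate(events):
        if kind == "insertion":
            for r in rs:
                if r in created_by:
                    return False  # a run cannot be inserted twice
                created_by[r] = idx
    root_state = frozenset(r for r in range(m) if r not in created_by)

    by_branch: dict[int, list] = {}
    for e in events:
        by_branch.setdefault(e[1], []).append(e)

    def apply_orders(state, evs):
        """All reachable end states trying every order; returns a state or
        None (end state is order-independent, feasibility is not)."""
        for perm in itertools.permutations(evs):
            s = set(state)
            ok = True
            for kind, _b, rs in perm:
                lo, hi = min(rs), max(rs)
                between_present = {k for k in range(lo, hi + 1) if k in s}
                if kind == "deletion":
                    if not rs <= s or between_present != set(rs):
                        ok = False
                        break
                    s -= rs
                else:
                    if rs & s or between_present:
                        ok = False
                        break
                    s |= rs
            if ok:
                return frozenset(s)
        return None

    def walk(node, state):
        if node != 0 and node in by_branch:
            state = apply_orders(state, by_branch[node])
            if state is None:
                return False
        if not tree.children[node]:
            bit = 1 << tree.leaf_bit(tree.label[node])
            want = frozenset(r for r in range(m) if patterns[r][0] & bit)
            return state == want
        return all(walk(c, state) for c in tree.children[node])

    return walk(0, root_state)


def oracle_parsimonious_histories(block, tree: PhyloTree, max_events: int = 6):
    """All minimum-size event sets reproducing the block's gap pattern.

    Candidate events are filtered by two sound conditions: an insertion of
    run r on branch b needs pattern(r) a subset of clade(b) (the run can
    exist only below its origin), and a deletion of r on b needs pattern(r)
    disjoint from clade(b) (nothing re-creates a deleted run).  Every valid
    history satisfies both, so the filter loses nothing.
    """
    patterns = block_patterns(block, tree)
    m = len(patterns)
    run_sets = []
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            run_sets.append(frozenset(combo))

    candidates = []
    for b in tree.branches():
        mask = tree.mask(b)
        for rs in run_sets:
            if all(patterns[r][0] | mask == mask for r in rs):
                candidates.append(("insertion", b, rs))
            if all(patterns[r][0] & mask == 0 for r in rs):
                candidates.append(("deletion", b, rs))

    for k in range(0, max_events + 1):
        found = set()
        for combo in itertools.combinations(candidates, k):
            # no run handled twice by the same kind on overlapping sets
            if _replays(combo, patterns, tree):
                found.add(frozenset(combo))
        if found:
            return found
    return set()


def history_key(history):
    """Canonical key of a package IndelHistory for comparison."""
    return frozenset((e.kind, e.branch, frozenset(e.runs)) for e in history.events)


# ---------------------------------------------------------------------------
# Exhaustive pruning likelihood
# ---------------------------------------------------------------------------

def oracle_substitution_loglik(msa, tree: PhyloTree) -> float:
    """Sum over all ancestral state assignments, column by column."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaves = {tree.label[i]: i for i in range(tree.n_nodes) if not tree.children[i]}
    row_of = {n: i for i, n in enumerate(msa.names)}

    def p(t, x, y):
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        return same if x == y else (1 - same) / 3

    total = 0.0
    for j in range(len(msa.rows[0])):
        col_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            states = dict(zip(internal, assign))
            for name, node in leaves.items():
                ch = msa.rows[row_of[name]][j]
                states[node] = code.get(ch)  # None for gap/N
            lik = 0.25 if states[0] is not None else 1.0
            if states[0] is None:
                # root missing can only happen for a leaf-root; not used
                raise NotImplementedError
            for node in range(1, tree.n_nodes):
                x = states[tree.parent[node]]
                y = states[node]
                if y is None:
                    continue  # missing leaf: marginalized by summing nothing?
                lik *= p(tree.length[node], x, y)
            col_lik += lik
        total += np.log(col_lik)
    return float(total)
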