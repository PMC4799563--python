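"""Rooted phylogenies with branch lengths in expected substitutions per site.

Newick parsing is delegated to dendropy; the package keeps its own array
representation because every algorithm here (event inference, block
partitioning, pruning) wants parent pointers, preorder lists and clade
bitmasks rather than a general tree object.

Each non-root node identifies the branch above it, so "branch b" and "node
below b" are used interchangeably.  A trifurcating root is accepted and
treated as a hard root (no re-rooting); it is flagged on the object and in
the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .errors import MsaFormatError

logger = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """Rooted tree; node 0 is the root, nodes are in preorder."""

    parent: list  # parent[i] is the parent node id; None for the root
    length: list  # branch length above node i; 0.0 for the root
    children: list  # children[i]: list of child node ids
    label: list  # leaf name or None for internal nodes
    trifurcating_root: bool = False

    # derived, filled in __post_init__
    leaf_names: tuple = field(init=False)
    _leaf_bit: dict = field(init=False)
    _mask: list = field(init=False)

    def __post_init__(self):
        for i, t in enumerate(self.length):
            if i == 0:
                continue
            if t is None or t != t or t == float("inf"):
                raise MsaFormatError(f"branch above node {i} has no finite length")
            if t < 0:
                raise MsaFormatError(f"negative branch length at node {i}")
        leaves = [i for i in range(self.n_nodes) if not self.children[i]]
        names = [self.label[i] for i in leaves]
        if any(n is None for n in names) or len(set(names)) != len(names):
            raise MsaFormatError("leaves must carry unique labels")
        self.leaf_names = tuple(names)
        self._leaf_bit = {self.label[i]: k for k, i in enumerate(leaves)}
        self._mask = [0] * self.n_nodes
        for i in reversed(range(self.n_nodes)):  # preorder => reversed is postorder
            if not self.children[i]:
                self._mask[i] = 1 << self._leaf_bit[self.label[i]]
            else:
                m = 0
                for c in self.children[i]:
                    m |= self._mask[c]
                self._mask[i] = m

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def preorder(self) -> range:
        return range(self.n_nodes)

    def postorder(self) -> list:
        return list(reversed(range(self.n_nodes)))

    def branches(self) -> list:
        """Non-root node ids, each standing for the branch above it."""
        return list(range(1, self.n_nodes))

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_ids(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def node_of_leaf(self, name: str) -> int:
        for i in range(self.n_nodes):
            if self.label[i] == name:
                return i
        raise KeyError(name)

    def total_branch_length(self) -> float:
        return sum(self.length[i] for i in range(1, self.n_nodes))

    # -- clades as bitmasks over leaf_names order --------------------------

    def leaf_bit(self, name: str) -> int:
        return self._leaf_bit[name]

    def mask(self, node: int) -> int:
        """Bitmask of leaves under ``node`` (node itself if a leaf)."""
        return self._mask[node]

    @property
    def all_leaves_mask(self) -> int:
        return self._mask[0]

    def clade_names(self, node: int) -> frozenset:
        m = self._mask[node]
        return frozenset(n for n in self.leaf_names if m >> self._leaf_bit[n] & 1)

    def mask_names(self, mask: int) -> frozenset:
        return frozenset(n for n in self.leaf_names if mask >> self._leaf_bit[n] & 1)

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when ``a`` is an ancestor of (or equal to) ``b``."""
        while b is not None:
            if b == a:
                return True
            b = self.parent[b]
        return False

    def mrca_node(self, nodes) -> int:
        """Most recent common ancestor of a non-empty set of node ids."""
        nodes = list(nodes)
        anc = nodes[0]
        for b in nodes[1:]:
            while not self.is_ancestor(anc, b):
                anc = self.parent[anc]
        return anc

    def subtree_nodes(self, node: int) -> list:
        out = [node]
        stack = list(self.children[node])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    def path_to_root(self, node: int) -> list:
        out = []
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                core = self.label[i]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if i == 0:
                return core + ";"
            return f"{core}:{self.length[i]:g}"

        return rec(0)


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    seed = dtree.seed_node
    parent, length, children, label = [], [], [], []
    ids = {}

    def add(node, par):
        i = len(parent)
        ids[node] = i
        parent.append(par)
        if par is None:
            length.append(0.0)
        else:
            if node.edge.length is None:
                raise MsaFormatError("newick: a branch is missing its length")
            length.append(float(node.edge.length))
        children.append([])
        label.append(node.taxon.label if node.taxon is not None else None)
        if par is not None:
            children[par].append(i)
        for ch in node.child_nodes():
            add(ch, i)

    add(seed, None)
    tri = len(seed.child_nodes()) > 2
    if tri:
        logger.warning(
            "tree has a trifurcating root; treating it as a hard root "
            "(no re-rooting)"
        )
    return PhyloTree(parent, length, children, label, trifurcating_root=tri)


def read_tree_newick(path) -> PhyloTree:
    """Read a rooted Newick tree; every branch must carry a length."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise MsaFormatError(f"{path}: cannot parse newick ({exc})") from exc
    return _from_dendropy(dtree)


def tree_from_newick(text: str) -> PhyloTree:
    """Parse a Newick string (same contract as :func:`read_tree_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise MsaFormatError(f"cannot parse newick ({exc})") from exc
    return _from_dendropy(dtree)


def check_leaves_match(tree: PhyloTree, names) -> None:
    if set(tree.leaf_names) != set(names):
        raise MsaFormatError(
            "tree leaves and alignment names differ: "
            f"{sorted(set(tree.leaf_names) ^ set(names))}"
        )
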