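"""Neutral DNA evolution along a tree with power-law indels.

The simulator evolves a root sequence down a rooted tree under a
Gillespie-style continuous-time process.  Indels occur at total rate
(lambda_ins + lambda_del) * L(t) where L(t) is the current sequence length;
event lengths follow a Zipf (discrete power-law) distribution truncated at a
cutoff; substitutions follow Jukes-Cantor.  Every residue ever created is
tracked as a token with a global ordering, so the assembled alignment of the
leaves is the *true* MSA: its columns are exact homology classes, including
columns created by insertions on internal branches and carved up by later
deletions.

Defaults are the study conditions this package is built around: a 1000-base
root, Jukes-Cantor substitutions, insertion rate = deletion rate = 0.0625
events per site per unit branch length (0.125 total, branch lengths in
substitutions/site), and Zipf exponent 1.6 with length cutoff 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import zeta

from .errors import DomainError, SimulationError
from .msa import Msa, canonicalize
from .phylo import PhyloTree

_BASES = "ACGT"
_HEAD = -1  # sentinel token heading the global order


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------

class ZipfIndelLength:
    """Zipf power-law length distribution f(l) proportional to l^(-a).

    With a finite ``cutoff`` c the pmf is renormalized over 1..c (lengths
    must never exceed the cutoff, so truncated normalization keeps a proper
    pmf).  ``cutoff=None`` is the analysis mode with the infinite-sum
    normalizer 1/zeta(a); it supports pmf evaluation but not sampling.
    """

    def __init__(self, exponent: float = 1.6, cutoff: int | None = 100):
        if exponent <= 1.0:
            raise DomainError("Zipf exponent must exceed 1 for normalizability")
        if cutoff is not None and cutoff < 1:
            raise DomainError("cutoff must be >= 1")
        self.exponent = float(exponent)
        self.cutoff = cutoff
        if cutoff is None:
            self._norm = float(zeta(exponent, 1))
            self._pmf = None
            self._cum = None
        else:
            raw = np.arange(1, cutoff + 1, dtype=float) ** (-exponent)
            self._norm = float(raw.sum())
            self._pmf = raw / self._norm
            self._cum = np.cumsum(self._pmf)

    def pmf(self, l) -> float | np.ndarray:
        l_arr = np.asarray(l)
        hi = np.inf if self.cutoff is None else self.cutoff
        if np.any(l_arr < 1) or np.any(l_arr > hi):
            raise DomainError(f"length {l} outside 1..{hi}")
        return np.asarray(l_arr, dtype=float) ** (-self.exponent) / self._norm

    def mean(self) -> float:
        if self.cutoff is None:
            return float(zeta(self.exponent - 1, 1)) / self._norm
        return float(np.arange(1, self.cutoff + 1) @ self._pmf)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.cutoff is None:
            raise DomainError("sampling requires a finite cutoff")
        u = rng.random(size)
        return np.searchsorted(self._cum, u) + 1


def zipf_length_pmf(model: ZipfIndelLength, l: int) -> float:
    """Normalized pmf value f(l) of the indel length law."""
    return float(model.pmf(l))


@dataclass(frozen=True)
class IndelModel:
    """Insertion/deletion rates per site per unit branch length."""

    ins_rate: float = 0.0625
    del_rate: float = 0.0625
    length: ZipfIndelLength = field(default_factory=ZipfIndelLength)

    def __post_init__(self):
        if self.ins_rate < 0 or self.del_rate < 0:
            raise DomainError("indel rates must be non-negative")

    @property
    def total_rate(self) -> float:
        return self.ins_rate + self.del_rate


class JukesCantor:
    """Jukes-Cantor substitution model: uniform base frequencies, one rate."""

    pi = np.full(4, 0.25)

    @staticmethod
    def rate_matrix() -> np.ndarray:
        q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(q, -1.0)
        return q

    @staticmethod
    def p_same(t: float) -> float:
        """Probability a site shows the same base after branch length t."""
        return 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)

    @staticmethod
    def p_matrix(t: float) -> np.ndarray:
        same = JukesCantor.p_same(t)
        diff = (1.0 - same) / 3.0
        p = np.full((4, 4), diff)
        np.fill_diagonal(p, same)
        return p


DEFAULT_SUBST = JukesCantor()
DEFAULT_INDEL = IndelModel()


# ---------------------------------------------------------------------------
# Events and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimEvent:
    """One indel on a branch.

    ``anchor`` is the coordinate in the sequence as it stood when the event
    fired (insertion: slot in 0..L; deletion: first removed site in 0..L-1),
    which is the frame event replay consumes.  ``tokens`` are the global ids
    the event created or removed.
    """

    kind: str  # "insertion" | "deletion"
    time: float
    anchor: int
    length: int
    tokens: tuple[int, ...]


@dataclass
class SimResult:
    """A simulated true MSA plus the complete event history behind it."""

    msa: Msa
    tree: PhyloTree
    events: dict  # node id -> list[SimEvent] on the branch above it
    node_tokens: dict  # node id -> list of token ids (sequence at the node)
    leaf_sequences: dict  # leaf name -> ungapped string
    seed: int | None


def replay_events(parent_tokens: list, events: list[SimEvent],
                  next_fresh: int | None = None) -> list:
    """Apply a branch's event list to a parent token sequence.

    Returns the child token list; used to verify that the logged history
    reproduces every node sequence exactly.
    """
    seq = list(parent_tokens)
    for ev in events:
        if ev.kind == "insertion":
            seq[ev.anchor:ev.anchor] = list(ev.tokens)
        else:
            removed = seq[ev.anchor:ev.anchor + ev.length]
            if tuple(removed) != ev.tokens:
                raise SimulationError("event log does not replay")
            del seq[ev.anchor:ev.anchor + ev.length]
    return seq


# ---------------------------------------------------------------------------
# Core engine
# ---------------------------------------------------------------------------

def _splice(nxt: dict, left: int, new_ids: list) -> None:
    """Insert ``new_ids`` into the global order right after token ``left``."""
    tail = nxt[left]
    prev = left
    for t in new_ids:
        nxt[prev] = t
        prev = t
    nxt[prev] = tail


def _evolve_branch_tokens(seq_in, bases_in, t_branch, indel, rng, fresh, nxt):
    """Indels then substitutions on one branch, at token resolution.

    ``fresh`` is a one-element list holding the next unused token id; ``nxt``
    is the global order (mutated in place when insertions create tokens).
    Substitutions are applied to every surviving token over the full branch
    length; tokens inserted mid-branch take a uniform base, and because the
    uniform distribution is stationary under Jukes-Cantor, applying the full
    branch transition to them too leaves their distribution unchanged.
    """
    seq = list(seq_in)
    bases = list(bases_in)
    events: list[SimEvent] = []
    lam = indel.total_rate
    t = 0.0
    while lam > 0.0:
        L = len(seq)
        if L == 0:
            raise SimulationError("sequence deleted to length 0; rerun with a new seed")
        t += rng.exponential(1.0 / (lam * L))
        if t >= t_branch:
            break
        length = int(indel.length.sample(rng))
        if rng.random() < indel.ins_rate / lam:
            slot = int(rng.integers(0, L + 1))
            new_ids = list(range(fresh[0], fresh[0] + length))
            fresh[0] += length
            left = seq[slot - 1] if slot > 0 else _HEAD
            _splice(nxt, left, new_ids)
            seq[slot:slot] = new_ids
            bases[slot:slot] = list(rng.integers(0, 4, length))
            events.append(SimEvent("insertion", t, slot, length, tuple(new_ids)))
        else:
            site = int(rng.integers(0, L))
            removed = seq[site:site + length]  # right-end overhang truncates
            del seq[site:site + length]
            del bases[site:site + length]
            events.append(SimEvent("deletion", t, site, len(removed), tuple(removed)))

    if seq and t_branch > 0:
        arr = np.asarray(bases)
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t_branch / 3.0))
        hit = rng.random(arr.size) < p_change
        n_hit = int(hit.sum())
        if n_hit:
            arr[hit] = (arr[hit] + rng.integers(1, 4, n_hit)) % 4
        bases = arr.tolist()
    return seq, bases, events


def evolve_branch(seq: str, t_branch: float,
                  subst: JukesCantor = DEFAULT_SUBST,
                  indel: IndelModel = DEFAULT_INDEL,
                  rng: np.random.Generator | None = None):
    """Evolve one nucleotide string over one branch.

    Returns (child sequence, event list); anchors are in the frame of the
    sequence at event time, so replaying the events from the parent string
    reproduces the child's token layout.
    """
    if t_branch < 0:
        raise DomainError("branch length must be non-negative")
    if not seq:
        raise DomainError("empty input sequence")
    rng = np.random.default_rng() if rng is None else rng
    base_of = {c: i for i, c in enumerate(_BASES)}
    tokens = list(range(len(seq)))
    bases = [base_of[c] for c in seq.upper()]
    # single-branch call: the global order is throwaway bookkeeping
    nxt = {t: None for t in [_HEAD] + tokens}
    fresh = [len(seq)]
    child, child_bases, events = _evolve_branch_tokens(
        tokens, bases, t_branch, indel, rng, fresh, nxt
    )
    return "".join(_BASES[b] for b in child_bases), events


def simulate_true_msa(tree: PhyloTree, root_length: int = 1000,
                      subst: JukesCantor = DEFAULT_SUBST,
                      indel: IndelModel = DEFAULT_INDEL,
                      seed=None, max_retries: int = 10,
                      canonical: bool = True) -> SimResult:
    """Simulate a true MSA along ``tree`` under the neutral indel model.

    The root is drawn i.i.d. from the base frequencies; branches are evolved
    in preorder; the alignment is assembled from the complete token history
    (deleted residues included while they separate surviving ones) and
    canonicalized.  A lineage shrinking to zero length aborts the replicate;
    it is retried with a fresh seed stream up to ``max_retries`` times, and
    the retry count is visible through the recorded seed.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    last_err: SimulationError | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(ss.spawn(1)[0])
        try:
            return _simulate_once(tree, root_length, indel, rng, seed, canonical)
        except SimulationError as err:
            last_err = err
    raise SimulationError(
        f"simulation failed {max_retries} times (lineage deleted to length 0): {last_err}"
    )


def _simulate_once(tree, root_length, indel, rng, seed, canonical) -> SimResult:
    root_tokens = list(range(root_length))
    root_bases = list(rng.integers(0, 4, root_length))
    nxt = {_HEAD: 0 if root_length else None}
    for i in range(root_length - 1):
        nxt[i] = i + 1
    if root_length:
        nxt[root_length - 1] = None
    fresh = [root_length]

    node_tokens = {0: root_tokens}
    node_bases = {0: root_bases}
    events: dict = {}
    for node in tree.preorder():
        if node == 0:
            continue
        par = tree.parent[node]
        toks, bases, evs = _evolve_branch_tokens(
            node_tokens[par], node_bases[par], tree.length[node],
            indel, rng, fresh, nxt,
        )
        node_tokens[node] = toks
        node_bases[node] = bases
        events[node] = evs

    # Assemble the leaf alignment from the global token order.
    leaf_ids = tree.leaf_ids()
    leaf_names = [tree.label[i] for i in leaf_ids]
    leaf_maps = [dict(zip(node_tokens[i], node_bases[i])) for i in leaf_ids]
    present: set = set()
    for m in leaf_maps:
        present.update(m.keys())

    cols = []
    tok = nxt[_HEAD]
    while tok is not None:
        if tok in present:
            cols.append(tok)
        tok = nxt.get(tok)

    rows = []
    for m in leaf_maps:
        rows.append("".join(_BASES[m[t]] if t in m else "-" for t in cols))
    msa = Msa(tuple(leaf_names), tuple(rows))
    if canonical:
        msa = canonicalize(msa)
    return SimResult(
        msa=msa, tree=tree, events=events, node_tokens=node_tokens,
        leaf_sequences={n: r.replace("-", "") for n, r in zip(leaf_names, rows)},
        seed=seed,
    )
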