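"""Complete-likelihood score, stand-in aligner score and D/I/S categories.

The complete-likelihood score of an alignment is the log of its joint
occurrence probability under the evolutionary model, and it decomposes
additively into

* the **substitution component** — the classic log-likelihood of the residue
  configuration, computed exactly by Felsenstein pruning under Jukes-Cantor
  with gaps and N treated as missing data; and
* the **indel component** — the log probability of the gap configuration:
  the alignment is chopped into gapped and gapless segments, every gapped
  segment contributes the summed weight of its parsimonious indel histories,
  and a global factor covers the probability that nothing else happened.

Comparing an erroneous segment's true and reconstructed alignments under
both this score and an aligner-style objective yields the three broad error
categories: **S** (the truth does not outscore the reconstruction in
complete likelihood — stochastic evolution made the truth sub-optimal),
**I** (the truth outscores it under both scores — the aligner's search
missed it) and **D** (the truth wins in complete likelihood but not in the
aligner's own score — the two objectives disagree).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, IntractableSegmentError
from .msa import GAP, AlnBlock, gap_segmentation
from .phylo import PhyloTree, check_leaves_match
from .sim import IndelModel, JukesCantor
from .histories import (
    enumerate_parsimonious_histories,
    weight_ensemble,
)

SCORE_EPSILON = 1e-5


# ---------------------------------------------------------------------------
# Substitution component (Felsenstein pruning, JC)
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def substitution_component(msa, tree: PhyloTree,
                           subst: JukesCantor = JukesCantor()) -> float:
    """Log-likelihood of the residue configuration via post-order pruning.

    Gap and N cells carry partial likelihood 1 for every state (missing
    data), so an all-gap column contributes log 1 = 0.
    """
    check_leaves_match(tree, msa.names)
    n_cols = len(msa.rows[0])
    row_of = {n: i for i, n in enumerate(msa.names)}

    partial = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            row = msa.rows[row_of[tree.label[node]]]
            p = np.empty((n_cols, 4))
            for j, ch in enumerate(row):
                if ch in _CODE:
                    p[j] = 0.0
                    p[j, _CODE[ch]] = 1.0
                else:  # gap or N: missing
                    p[j] = 1.0
            partial[node] = p
        else:
            p = np.ones((n_cols, 4))
            for c in tree.children[node]:
                pm = JukesCantor.p_matrix(tree.length[c])
                p *= partial.pop(c) @ pm.T
            partial[node] = p
    lik = partial[0] @ JukesCantor.pi
    with np.errstate(divide="ignore"):
        return float(np.log(lik).sum())


# ---------------------------------------------------------------------------
# Indel component
# ---------------------------------------------------------------------------

def overall_indel_factor_log(n_cols: int, tree: PhyloTree,
                             indel: IndelModel) -> float:
    """log Phi = -(lambda_ins + lambda_del) * n_cols * total branch length.

    First-order probability that a sequence of the alignment's size escapes
    further indels; it nearly cancels between two alignments of the same
    sequences, which is all the score comparisons need.
    """
    return -indel.total_rate * n_cols * tree.total_branch_length()


def indel_component(msa, tree: PhyloTree,
                    indel: IndelModel = IndelModel(),
                    max_histories: int | None = None,
                    max_events: int | None = None) -> float:
    """Log probability of the gap configuration.

    log Phi plus, per gapped segment, the log of the summed parsimonious
    history weights.  A segment whose enumeration exceeds the caps raises
    :class:`IntractableSegmentError` naming the segment so the caller can
    exclude it; an impossible gap configuration (e.g. gaps with zero indel
    rates) yields -inf.
    """
    check_leaves_match(tree, msa.names)
    kw = {}
    if max_histories is not None:
        kw["max_histories"] = max_histories
    if max_events is not None:
        kw["max_events"] = max_events
    total = overall_indel_factor_log(len(msa.rows[0]), tree, indel)
    for a, b in gap_segmentation(msa).gapped_spans:
        block = AlnBlock(msa.names, tuple(r[a:b] for r in msa.rows))
        try:
            ens = enumerate_parsimonious_histories(block, tree, **kw)
        except IntractableSegmentError as err:
            raise IntractableSegmentError(
                f"gapped segment [{a},{b}) intractable: {err}", partial=err.partial
            ) from err
        ens = weight_ensemble(ens, indel, tree)
        z = ens.normalization
        total += math.log(z) if z > 0 else float("-inf")
    return total


# ---------------------------------------------------------------------------
# Complete likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompleteLikelihood:
    """Indel + substitution log components; total is their exact sum."""

    indel_component: float
    substitution_component: float

    @property
    def total(self) -> float:
        return self.indel_component + self.substitution_component


def complete_likelihood_score(msa, tree: PhyloTree,
                              subst: JukesCantor = JukesCantor(),
                              indel: IndelModel = IndelModel(),
                              **caps) -> CompleteLikelihood:
    """Both components of the complete-likelihood score of one alignment."""
    return CompleteLikelihood(
        indel_component=indel_component(msa, tree, indel, **caps),
        substitution_component=substitution_component(msa, tree, subst),
    )


# ---------------------------------------------------------------------------
# Stand-in aligner-specific score
# ---------------------------------------------------------------------------

def standin_aligner_score(msa, match: float = 1.0, mismatch: float = -1.0,
                          gap_open: float = -4.0, gap_extend: float = -0.5,
                          free_end_gaps: bool = False) -> float:
    """Sum-of-pairs score with affine gap penalties.

    A deterministic stand-in for an aligner's internal objective: for every
    sequence pair, columns where both rows show residues score match or
    mismatch, and each maximal gap run in the pairwise projection (columns
    where exactly one row has a residue) costs gap_open + length*gap_extend.
    ``free_end_gaps`` waives runs touching either end of the pair projection.
    N matches nothing and mismatches nothing (scores 0).
    """
    score = 0.0
    n = len(msa.rows)
    for i, j in itertools.combinations(range(n), 2):
        ri, rj = msa.rows[i], msa.rows[j]
        cols = [(a, b) for a, b in zip(ri, rj) if not (a == GAP and b == GAP)]
        runs = []  # (start, length) of single-sided gap runs
        cur = None
        for k, (a, b) in enumerate(cols):
            if (a == GAP) != (b == GAP):
                if cur is None:
                    cur = [k, 0]
                cur[1] += 1
            else:
                if cur is not None:
                    runs.append(tuple(cur))
                    cur = None
                if a != "N" and b != "N":
                    score += match if a == b else mismatch
        if cur is not None:
            runs.append(tuple(cur))
        for start, length in runs:
            if free_end_gaps and (start == 0 or start + length == len(cols)):
                continue
            score += gap_open + length * gap_extend
    return score


# ---------------------------------------------------------------------------
# D/I/S categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreComparison:
    """The four scores of one erroneous segment and their category."""

    l_true: float
    l_rec: float
    s_true: float
    s_rec: float
    epsilon: float = SCORE_EPSILON

    @property
    def category(self) -> str:
        return categorize_DIS(self.l_true, self.l_rec, self.s_true, self.s_rec,
                              self.epsilon)


def categorize_DIS(l_true: float, l_rec: float, s_true: float, s_rec: float,
                   epsilon: float = SCORE_EPSILON) -> str:
    """Assign the broad score category of an erroneous segment.

    S when the true alignment does not outscore the reconstruction in
    complete likelihood (within epsilon); otherwise I when it also wins
    under the aligner-specific score; otherwise D.  The three categories
    partition all finite score quadruples.
    """
    for v in (l_true, l_rec, s_true, s_rec):
        if not math.isfinite(v):
            raise InputError("D/I/S categorization needs four finite scores")
    if l_true <= l_rec + epsilon:
        return "S"
    if s_true > s_rec + epsilon:
        return "I"
    return "D"
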