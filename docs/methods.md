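# Methods

This note records the models, conventions and design choices behind
`alignerr`, in the order data flows through the package.

## Evolutionary model and simulator

Sequences evolve neutrally down a rooted tree whose branch lengths are
expected substitutions per site. Defaults are the package's study
conditions throughout:

| parameter | default | meaning |
|---|---|---|
| root length | 1000 bases | i.i.d. uniform root sequence |
| substitution model | Jukes–Cantor | uniform base frequencies, one rate |
| insertion rate λ_ins | 0.0625 /site/unit length | events, not bases |
| deletion rate λ_del | 0.0625 /site/unit length | total indel rate 0.125 per substitution |
| indel length law | Zipf, exponent 1.6 | f(l) ∝ l^−1.6 |
| length cutoff | 100 | truncated renormalization over 1..100 |

Indels follow a Gillespie process at total rate
(λ_ins + λ_del) · L(t) with L(t) the current sequence length. An
insertion picks one of the L+1 inter-site slots uniformly (both ends
included); a deletion anchors uniformly on a site and truncates at the
right sequence end when it overhangs. The length law is renormalized over
1..cutoff — lengths must never exceed the cutoff, and a proper pmf is
needed for history weights; an infinite-sum mode (normalizer 1/ζ(a)) is
available for analysis but not for sampling. A lineage shrinking to zero
length aborts the replicate, which is retried under a fresh seed stream.

Every residue ever created is a *token* with a position in one global
order; insertions splice new tokens into that order, deletions remove them
from a lineage but not from the order. The leaf alignment assembled from
the surviving tokens is therefore the exactly-known true MSA: columns are
homology classes, including insertion-born columns later carved up by
deletions. Substitutions are applied per surviving site over the full
branch after the indel pass; a residue inserted mid-branch takes a uniform
random base at the branch end, which is distributionally identical to
drawing at insertion time and evolving the remainder because the uniform
distribution is stationary under Jukes–Cantor. Every stochastic entry
point takes an explicit seed (numpy `SeedSequence` spawning), and replaying
a branch's logged events from the parent token list reproduces the child
exactly (anchors are recorded in the sequence frame current at event time,
which is the frame replay consumes).

### Study trees

The three divergence regimes are represented by embedded trees with 12, 9
and 15 leaves and total branch lengths 0.384, 2.279 and 1.539. Only
summary statistics of the original study trees are available (leaf counts,
totals, external/internal branch-length means and spreads), so these are
representative reconstructions: fixed topologies whose external and
internal branch lengths scatter around the recorded means and are scaled
to the exact totals. Segment-level statistics of the neutral indel process
are governed by the total rate and the leaf count rather than fine
topology, which is what makes the stand-ins serviceable; a residual
systematic offset at the percent level is expected and observed.

### What the simulator reproduces — and what it does not

At the study conditions the simulator matches the reference gapped-segment
totals within ~1% (per-MSA means ≈96.0/103.1-expected/40.4 for the
moderate/large/small regimes) and the expected gapless-segment length for
the large-divergence regime (≈4.05 vs the reference ≈4.0). Two statistics
deviate: the mean *gapped*-segment length measures ≈14.2 columns against a
reference closed-form estimate of ≈11.9, and the share of gapped segments
containing an over-100-column apparent indel measures ≈2.4% against a
reference value of 1.9%. Segment counts and gapless spacing pin down the event-rate
conventions (they depend only on event endpoints), whereas gapped-segment
length requires the full distribution of overlapping, compounded indel
intervals — exactly what a first-order coverage argument underestimates —
and the long-run share moves the same direction. Both numbers are reported
as measured; no parameter is tuned toward them.

The simulator emulates neutral substitutions and indels only: no rate
heterogeneity, selection, inversions, duplications or microsatellite
dynamics. Conclusions drawn from fixtures therefore speak to gap-placement
errors under neutral evolution, not to every failure mode of real data.

## Canonical form and segmentation

Aligners infer only the *homology structure* of an alignment — which
residues share a column — not the order of columns whose mutual order the
sequences do not constrain. `canonicalize` removes all-gap columns and
linearizes the column partial order greedily: among ready columns, the one
containing the residue of the lowest row index is emitted first, ties
broken by the lowest residue ordinal. The map is idempotent and any two
alignments with equal homology structure become byte-identical, so all
downstream comparisons are string comparisons. `N` counts as missing data
for likelihoods but as a residue for gap segmentation.

A pair of canonical alignments of the same sequences is anchored on
columns that are gapless in both and homologize identical residue
ordinals. Maximal anchor runs (plus inter-anchor regions where the two
alignments agree byte-for-byte, which the greedy canonical order makes a
sound test) form correct segments; disagreeing regions form erroneous
segments, delimited by anchors or by the alignment termini. Labels
strictly alternate and segments tile every sequence's residues. A single
anchor column suffices as a delimiter. Erroneous segments in which either
alignment shows a single-row gap run longer than 100 columns are flagged
intractable and excluded from analysis; the threshold is strict
("over 100": a run of exactly 100 is kept).

## Position-shift maps and blocks

Within one erroneous segment, a residue's shift is its (reconstructed −
true) column index, both segment-local so the background is 0 regardless
of upstream length differences. The map can be drawn on either alignment
(default: the reconstruction); the values do not change with the canvas,
and swapping which alignment plays "true" negates them. Per row, maximal
runs of consecutive same-shift residues merge across rows into blocks when
their column spans overlap and the rows are phylogenetically connected:
every other leaf inside the clade spanned by the two rows either carries
the same shift in the overlap or has only gaps there. This connectivity
rule is the package's own operationalization of "contiguous along the
alignment and the phylogeny"; it guarantees single-branch-delimited blocks
in clean cases. Block length counts distinct columns spanned (sites).
Separation metrics per segment: number of blocks (block-wise moves),
summed block length (site-wise moves), longest block, with flags at ≥5
blocks, ≥30 sites and ≥30-column blocks. Sliding every block's residues
back by −shift reconstructs the other alignment's homology structure,
which is tested on all injected fixtures.

## Parsimonious indel histories

A gapped segment decomposes into maximal column runs with identical
presence/absence patterns. A history assigns each run an origin (ancestral
at the root, or an insertion on a branch whose clade covers the run's
pattern) plus a disjoint-subtree cover of its absences by deletions, and
merges same-branch same-kind atoms into single events when the runs in
between are absent from that lineage at firing time (that is what makes
two gaps adjacent *in the sequence* even when the alignment shows other
material between them). Enumeration is depth-first over per-run fates with
a branch-and-bound prune (a joint assignment can never use fewer events
than its number of distinct (kind, branch) groups), followed by
merge-partition search per group; validity of every candidate is confirmed
by replaying it down the tree with exhaustive per-branch event orderings.
All and only the minimum-event histories are kept. Run-splitting variants
(two same-branch events inside one run) are never count-parsimonious and
are not generated. Insertions on a virtual root stem are likewise never
generated: they always cost one event more than root ancestry with the
same deletions, and carry no defined branch length.

Caps make heavy segments fail fast rather than slowly: ≤10,000 tying
histories, ≤12 events, bounded assignment and search-node budgets, and a
14-atom limit per same-branch merge group (between 7 and 14 atoms only
consecutive-interval merge partitions are tried; a non-consecutive merged
event requires an interleaved same-branch event ordered before it, which
interval splits almost always cover). A capped segment raises an
intractability error carrying any partial ensemble; the pipeline skips it
and reports the reason, mirroring the long-indel screen.

A history's weight is ∏ events rate(kind) · f(length) · branch length,
with 1/k! per branch carrying k events (unordered same-branch events).
Exit-rate exponentials are deliberately moved wholesale into the
alignment-level overall factor: only weight *ratios* enter expected counts
and score comparisons, and there these leading-order factors dominate.
Events on zero-length branches, or longer than the length cutoff, get
weight 0 (impossible); impossible histories are dropped from the ensemble
unless all weights vanish.

Expected insertion/deletion counts are the weight-normalized averages over
the ensemble; per erroneous segment they sum over its gapped segments.
The misestimation measures between the reconstructed and true counts are
ordinary difference (sum of the two count differences), L1 distance (sum
of absolute differences) and deletion bias (difference of differences).

## Complete-likelihood score

`log P(MSA) = log Φ + Σ_gapped segments log Σ_histories weight +
substitution log-likelihood`, with Φ = exp(−(λ_ins+λ_del) · n_cols ·
total branch length) the first-order probability that a sequence of the
alignment's size escapes further indels. The exact overall factor is an
open modeling choice; this surrogate is monotone and length-sensitive, and
because compared alignments share sequences and nearly share width it
almost cancels in every comparison the categories consume. It is isolated
in one function and echoed in output metadata. The substitution component
is computed by Felsenstein pruning under Jukes–Cantor with gaps and N as
missing data (partial likelihood 1 in all states); additivity of the two
components is asserted exactly on every scored alignment.

The aligner-specific score is a stand-in: an affine sum-of-pairs score
(match 1, mismatch −1, gap open −4, extend −0.5 by default; terminal gaps
penalized unless waived) over all row pairs, with per-segment external
score ingestion available for users who have real aligner objectives. Two
scores tie when they differ by less than ε = 1e-5; ε applies to both score
families. Categories: **S** if the true alignment does not outscore the
reconstruction in complete likelihood; else **I** if it also wins the
aligner score; else **D**. The three cases partition all finite score
quadruples.

## Error classification

For each block, representative events (the max-weight parsimonious
history per gapped segment; ties prefer fewer insertions, then
lexicographic order) are computed for both alignments and restricted to a
window of the block's span widened by one pattern-run on each side, mapped
across coordinates through the block's residues. The decision table is
evaluated in order: exact matches cancel; equal signature multisets at
different positions → *shift*; then equal-signature pairs cancel
position-insensitively (repositioned neighbors caught in the window —
without this, any unrelated adjacent event poisons the counting rules);
then 2→1 same-branch merges (same-type: lengths add; opposite-type:
lengths subtract), 2→0 equal-length insertion/deletion pair → *purge*,
1→2 same-branch → *split*, 0→2 equal pair → *ex-nihilo*, same-type 2→1
onto the common ancestral branch with additive lengths → *vertical
merge* (reverse: *vertical split*), independent insertions 2→1 onto a
common ancestral branch → *CII* (reverse *CSII*), the same with residual
events → *iCII* (reverse *iCSII*), small overlapping remainders →
*other*, everything else → *complex*. Adjacent unclassified block pairs
get one rescue pass: the joint delta is matched whole (a merge-like joint
delta with two blocks reads as the named error plus a repositioning,
e.g. "merge + shift") or split across every bipartition into two named
sub-deltas.

Segments tally as their single label, as *mixture* (≥2 non-complex
labels; the subset explained by intrinsic pairs is the *paired* sub-row)
or as *complex* (≥1 unexplained block); percentages are over all
diagnosed segments.

### Injectable fixtures and the vertical types

The injector realizes ten error types by direct window surgery on a true
MSA (the reconstruction differs from the truth by exactly the named
error): shift, merge of same/opposite type, split, purge, ex-nihilo, CII,
iCII and their spurious-creation reverses CSII/iCSII. Targets are
restricted to clades that are not children of the root so the
representative history of every pattern involved is unambiguous.
*Vertical* merges and splits are not injectable: inside an anchored
segment, residue conservation forces the residues of (parent clade minus
child clade) to reappear as a residual run, so no alignment of the same
sequences exhibits the bare two-deletions-to-one vertical signature; the
classifier keeps the rule because window truncation can expose the pattern
in real data, but classifier validation covers the ten constructible
types. Fixture harvesting runs the simulator on a cherry-rich 8-leaf tree
under two indel-model conditions chosen for precondition frequency (the
balanced study rates for deletion-family types; an insertion-rich setting,
0.12/0.02, for the collapse family) — a validation-design choice that
changes how often targets occur, not what the classifier sees. Recovery
is ≥95% per type over ≥500 fixtures per type in the acceptance suite
(measured: 100% on every type at that scale).

## Numerical and degenerate-input conventions

Columns are 0-based half-open internally; reported positions (shift-map
and block tables) are 1-based. Trees must be rooted with finite
non-negative branch lengths on every non-root edge; a trifurcating root is
accepted as a hard root and flagged. A correct segment has no shift map
unless explicitly allowed (it would be identically zero). Gapless blocks
yield the single empty history with weight 1. Gap configurations that are
impossible under the model (e.g. any gap with both indel rates zero) score
−∞. Score ties use ε = 1e-5 throughout.

## Known limitations

* History weights are leading-order (no time-ordering integrals or local
  exit rates); they are accurate where weight ratios matter and are
  flagged as approximate in output metadata.
* The minimal move decomposition of interacting blocks is not sought; the
  block count is itself an approximation of the true move count.
* The gapped-segment mean length and long-indel share run above the
  reference closed-form estimates (see the simulator section); users reading
  those two statistics should treat the simulator's empirical values as
  the operative ones.
* Classification beyond the named taxonomy lands in *complex*; at large
  divergence that bucket dominates, as expected for entangled errors.
* DNA only (A,C,G,T,N); no protein models, no genomic rearrangements.
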