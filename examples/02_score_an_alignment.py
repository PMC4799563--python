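"""Compute the complete-likelihood score of a small alignment.

The score is the log joint probability of the alignment under the neutral
evolutionary model and splits exactly into an indel component (gap
configuration, via parsimonious indel histories) and a substitution
component (residue configuration, via Felsenstein pruning).
"""

from alignerr import Msa, complete_likelihood_score, tree_from_newick

tree = tree_from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
msa = Msa(("A", "B", "C"), ("ACGTACGT", "ACGTACGT", "ACG--CGT"))

cl = complete_likelihood_score(msa, tree)
print(f"indel component:        {cl.indel_component:.4f}")
print(f"substitution component: {cl.substitution_component:.4f}")
print(f"total:                  {cl.total:.4f}")
# The indel component sums, over the single gapped segment, the weights of
# its parsimonious explanations (a deletion on C's branch or an insertion
# on the AB stem) on top of a global no-further-indels factor; the
# substitution component is the ordinary JC log-likelihood with gaps
# treated as missing data.  The total is their exact sum.
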