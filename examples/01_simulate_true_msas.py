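"""Simulate true MSAs under the neutral indel model and count gap segments.

Builds the 15-leaf moderate-divergence study tree, evolves a 1000-base root
sequence down it (Jukes-Cantor substitutions; insertions and deletions at
0.0625 each per site per substitution unit with Zipf(1.6) lengths cut at
100), and reports the gapped-segment statistics of a few replicates.
"""

import numpy as np

from alignerr import gap_segmentation, simulate_true_msa
from alignerr.trees import mammals15

tree = mammals15()
print(f"tree: {tree.n_leaves} leaves, total branch length "
      f"{tree.total_branch_length():.3f} substitutions/site")

counts = []
for seed in np.random.SeedSequence(42).spawn(20):
    res = simulate_true_msa(tree, root_length=1000, seed=seed)
    seg = gap_segmentation(res.msa)
    counts.append(seg.n_gapped)

print(f"replicates: {len(counts)}")
print(f"mean gapped segments per true MSA: {np.mean(counts):.1f}")
print(f"alignment width of the last replicate: {res.msa.n_cols} columns")
# Each gapped segment is a maximal run of columns containing at least one
# gap; under these study conditions a 1000-base alignment accumulates close
# to a hundred of them, which is the raw material every downstream error
# analysis works through.
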