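"""Labeled single-error fixture generation shared by classifier tests.

Fixtures are harvested from neutral simulations on a cherry-rich 8-leaf
tree; two indel-model conditions make every error type's precondition
reasonably common (same-branch deletion pairs need deletions, independent
sibling insertions need insertions).  The injected label is the ground
truth the classifier is validated against.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from alignerr import classify, inject, segments, sim
from alignerr.phylo import tree_from_newick
from alignerr.sim import IndelModel

from tests.conftest import TREE8_NEWICK

# condition name -> (indel model, types harvested under it)
CONDITIONS = {
    "deletion_balanced": (
        IndelModel(0.0625, 0.0625),
        ("shift", "merge_same_type", "split"),
    ),
    "insertion_rich": (
        IndelModel(0.12, 0.02),
        ("CII", "iCII", "CSII", "iCSII", "purge", "merge_opposite_type",
         "ex_nihilo"),
    ),
}

ALL_TYPES = tuple(t for _, ts in CONDITIONS.values() for t in ts)

REVERSE_OF = {
    "merge_same_type": "split",
    "split": "merge_same_type",
    "purge": "ex_nihilo",
    "ex_nihilo": "purge",
    "CII": "CSII",
    "CSII": "CII",
    "iCII": "iCSII",
    "iCSII": "iCII",
    "shift": "shift",
}


def iter_fixtures(quota_per_type: int, seed: int = 97,
                  types=None, max_sims_per_condition: int = 4000,
                  per_sim_cap: int = 6, root_length: int = 1500):
    """Yield (tree, true_msa, rec_msa, label) fixtures up to the quotas."""
    tree = tree_from_newick(TREE8_NEWICK)
    wanted = set(types) if types is not None else set(ALL_TYPES)
    produced = defaultdict(int)
    for cond_idx, (model, cond_types) in enumerate(CONDITIONS.values()):
        todo = [t for t in cond_types if t in wanted]
        if not todo:
            continue
        ss = np.random.SeedSequence((seed, cond_idx))
        rng = np.random.default_rng((seed, 1))
        n_sims = 0
        while (n_sims < max_sims_per_condition
               and any(produced[t] < quota_per_type for t in todo)):
            child = ss.spawn(1)[0]
            n_sims += 1
            res = sim.simulate_true_msa(tree, root_length=root_length,
                                        indel=model, seed=child)
            info = inject.prepare_injection_info(res.msa, tree)
            for t in todo:
                if produced[t] >= quota_per_type:
                    continue
                targets = inject.find_targets(res.msa, tree, t, info=info)
                if len(targets) > per_sim_cap:
                    idx = rng.choice(len(targets), per_sim_cap, replace=False)
                    targets = [targets[i] for i in sorted(idx)]
                for tgt in targets:
                    if produced[t] >= quota_per_type:
                        break
                    try:
                        inj = inject.inject_elementary_error(res.msa, tree, tgt)
                    except Exception:
                        continue
                    produced[t] += 1
                    yield tree, res.msa, inj.rec, t


def classify_fixture(tree, true_msa, rec_msa, swap: bool = False):
    """Labels the classifier assigns to the (single) erroneous segment.

    Returns the set of block labels, or None when the pair does not reduce
    to exactly one erroneous segment.  ``swap`` reverses the roles of the
    two alignments (used for the reverse-label property).
    """
    a, b = (rec_msa, true_msa) if swap else (true_msa, rec_msa)
    series = segments.partition_into_segments(a, b)
    errs = series.erroneous()
    if len(errs) != 1:
        return None
    diag = classify.diagnose_segment(series, errs[0], tree)
    return set(diag.block_labels)


def recovery_counts(quota_per_type: int, seed: int = 97, types=None):
    """Per type: (n fixtures evaluated, n recovered exactly)."""
    stats = defaultdict(lambda: [0, 0])
    for tree, true_msa, rec_msa, label in iter_fixtures(
            quota_per_type, seed=seed, types=types):
        labels = classify_fixture(tree, true_msa, rec_msa)
        stats[label][0] += 1
        if labels == {label}:
            stats[label][1] += 1
    return {t: tuple(v) for t, v in stats.items()}
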