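"""End-to-end orchestration: compare, diagnose, score and report an MSA pair.

The pipeline canonicalizes the pair, chops it into correct/erroneous
segments, applies the long-indel tractability screen, and then per tractable
erroneous segment builds the shift map and blocks, classifies the blocks,
scores both sides (complete likelihood + stand-in aligner score, D/I/S),
and computes the probability-weighted indel counts with the three
misestimation measures.  Everything is deterministic given the inputs and
seeds; module-level errors mark a segment skipped and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import SegmentDiagnosis, diagnose_and_tally, diagnose_segment
from .errors import AlignerrError
from .histories import (
    IndelCounts,
    add_counts,
    enumerate_parsimonious_histories,
    expected_indel_counts,
    misestimation_measures,
    weight_ensemble,
)
from .likelihood import (
    SCORE_EPSILON,
    categorize_DIS,
    complete_likelihood_score,
    standin_aligner_score,
)
from .msa import AlnBlock, Msa, canonicalize, gap_segmentation
from .phylo import PhyloTree, check_leaves_match
from .segments import SegmentSeries, partition_into_segments, tractability_filter
from .shiftmap import build_position_shift_map, blocks_to_tsv, partition_shift_blocks
from .sim import IndelModel, JukesCantor, ZipfIndelLength

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and model parameters of one run (defaults are the study
    conditions: total indel rate 0.125 split evenly, Zipf(1.6) cut at 100,
    long-indel screen at 100, far-apart thresholds 5/30/30, score tie
    tolerance 1e-5)."""

    ins_rate: float = 0.0625
    del_rate: float = 0.0625
    zipf_exponent: float = 1.6
    zipf_cutoff: int = 100
    long_indel_threshold: int = 100
    block_steps_threshold: int = 5
    site_steps_threshold: int = 30
    long_block_threshold: int = 30
    epsilon: float = SCORE_EPSILON
    seed: int | None = None
    max_histories: int = 10_000
    max_events: int = 12

    def indel_model(self) -> IndelModel:
        return IndelModel(
            self.ins_rate, self.del_rate,
            ZipfIndelLength(self.zipf_exponent, self.zipf_cutoff),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SegmentReport:
    diagnosis: SegmentDiagnosis
    scores: dict | None = None  # l_true, l_rec, s_true, s_rec
    counts_true: IndelCounts | None = None
    counts_rec: IndelCounts | None = None
    skipped: str | None = None  # reason, when a module failed


@dataclass
class PairReport:
    series: SegmentSeries
    segment_reports: list
    n_excluded: int

    def diagnoses(self):
        return [r.diagnosis for r in self.segment_reports
                if r.diagnosis is not None]

    def category_proportions(self) -> dict:
        cats = [r.diagnosis.category for r in self.segment_reports
                if r.diagnosis is not None and r.diagnosis.category]
        n = len(cats)
        return {c: 100.0 * cats.count(c) / n for c in "DIS"} if n else {}


def _segment_counts(block: AlnBlock, tree, model, cfg) -> IndelCounts:
    total = IndelCounts(0.0, 0.0)
    for a, b in gap_segmentation(block).gapped_spans:
        sub = AlnBlock(block.names, tuple(r[a:b] for r in block.rows))
        ens = enumerate_parsimonious_histories(
            sub, tree, max_histories=cfg.max_histories, max_events=cfg.max_events
        )
        total = add_counts(total, expected_indel_counts(
            weight_ensemble(ens, model, tree)))
    return total


def run_pair(true_msa: Msa, rec_msa: Msa, tree: PhyloTree,
             config: RunConfig | None = None,
             external_scores: dict | None = None,
             with_scores: bool = True) -> PairReport:
    """Full per-segment analysis of one (true, reconstructed) pair.

    ``external_scores`` optionally maps a segment index to an
    (aligner score of true side, aligner score of rec side) pair, replacing
    the built-in sum-of-pairs stand-in for those segments.
    """
    cfg = config or RunConfig()
    model = cfg.indel_model()
    check_leaves_match(tree, true_msa.names)
    true_msa = canonicalize(true_msa)
    rec_msa = canonicalize(rec_msa)
    series = partition_into_segments(true_msa, rec_msa)
    series, n_excluded = tractability_filter(series, cfg.long_indel_threshold)

    reports = []
    for seg in series.erroneous():
        if not seg.tractable:
            reports.append(SegmentReport(
                diagnosis=None, skipped="long apparent indel (intractable)"))
            continue
        try:
            diag = diagnose_segment(series, seg, tree, model,
                                    max_histories=cfg.max_histories,
                                    max_events=cfg.max_events)
        except AlignerrError as err:
            logger.warning("segment %d skipped: %s", seg.index, err)
            reports.append(SegmentReport(diagnosis=None, skipped=str(err)))
            continue
        rep = SegmentReport(diagnosis=diag)

        tb = series.true_block(seg)
        rb = series.rec_block(seg)
        try:
            rep.counts_true = _segment_counts(tb, tree, model, cfg)
            rep.counts_rec = _segment_counts(rb, tree, model, cfg)
            diag.misestimation = misestimation_measures(rep.counts_true,
                                                        rep.counts_rec)
        except AlignerrError as err:
            logger.warning("segment %d counts unavailable: %s", seg.index, err)

        if with_scores:
            try:
                lt = complete_likelihood_score(
                    tb, tree, indel=model,
                    max_histories=cfg.max_histories, max_events=cfg.max_events)
                lr = complete_likelihood_score(
                    rb, tree, indel=model,
                    max_histories=cfg.max_histories, max_events=cfg.max_events)
                if external_scores and seg.index in external_scores:
                    st, sr = external_scores[seg.index]
                else:
                    st = standin_aligner_score(tb)
                    sr = standin_aligner_score(rb)
                rep.scores = {
                    "l_true": lt.total, "l_rec": lr.total,
                    "s_true": st, "s_rec": sr,
                }
                diag.category = categorize_DIS(lt.total, lr.total, st, sr,
                                               cfg.epsilon)
            except AlignerrError as err:
                logger.warning("segment %d scores unavailable: %s", seg.index, err)
        reports.append(rep)
    return PairReport(series=series, segment_reports=reports,
                      n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_reports(report: PairReport, outdir, tree: PhyloTree,
                  config: RunConfig | None = None) -> None:
    """Write the standard report files for one analyzed pair.

    segments.tsv, blocks.tsv, diagnoses.tsv, tally.tsv/json,
    dis_proportions.json, misestimation_hist.tsv and config.yaml.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    series = report.series
    series.to_tsv(out / "segments.tsv")
    (config or RunConfig()).to_yaml(out / "config.yaml")

    cfg = config or RunConfig()
    model = cfg.indel_model()
    with open(out / "blocks.tsv", "w") as fh:
        fh.write("segment\tshift\tcol_start\tcol_end\tlength\tsequences\n")
        for seg, rep in zip(series.erroneous(), report.segment_reports):
            if rep.diagnosis is None:
                continue
            try:
                smap = build_position_shift_map(series, seg)
                for b in partition_shift_blocks(smap, tree):
                    fh.write(
                        f"{seg.index}\t{b.shift}\t{b.col_span[0] + 1}\t"
                        f"{b.col_span[1]}\t{b.length}\t" + ",".join(sorted(b.rows)) + "\n"
                    )
            except AlignerrError:
                continue

    with open(out / "diagnoses.tsv", "w") as fh:
        fh.write(
            "segment\tclass\tlabels\tpaired\tcategory\tn_blocks\t"
            "site_moves\tmax_block\tordinary_diff\tl1\tdeletion_bias\tskipped\n"
        )
        for rep in report.segment_reports:
            d = rep.diagnosis
            if d is None:
                fh.write(f"-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\t{rep.skipped}\n")
                continue
            m = d.metrics
            mis = d.misestimation
            fh.write(
                f"{d.segment_index}\t{d.segment_class}\t"
                f"{','.join(d.block_labels)}\t{int(d.paired)}\t"
                f"{d.category or '-'}\t{m.n_blocks}\t{m.total_path_length}\t"
                f"{m.max_block_length}\t"
                + (f"{mis.ordinary_difference:.4f}\t{mis.l1_distance:.4f}\t"
                   f"{mis.deletion_bias:.4f}" if mis else "-\t-\t-")
                + "\t-\n"
            )

    tally = diagnose_and_tally(report.diagnoses())
    tally.to_csv(out / "tally.tsv", sep="\t", index=False)
    tally.to_json(out / "tally.json", orient="records")

    with open(out / "dis_proportions.json", "w") as fh:
        json.dump(report.category_proportions(), fh, indent=1)

    _misestimation_hist(report, out / "misestimation_hist.tsv")


def _misestimation_hist(report: PairReport, path) -> None:
    """2-D histogram of (L1 distance class, deletion bias class)."""
    def clas(x: float) -> int:
        return int(round(x))

    cells: dict = {}
    for rep in report.segment_reports:
        d = rep.diagnosis
        if d is None or d.misestimation is None:
            continue
        key = (clas(d.misestimation.l1_distance),
               clas(d.misestimation.deletion_bias))
        cells[key] = cells.get(key, 0) + 1
    with open(path, "w") as fh:
        fh.write("l1_class\tbias_class\tcount\n")
        for (l1, bias), n in sorted(cells.items()):
            fh.write(f"{l1}\t{bias}\t{n}\n")
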