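"""Scoring of predicted transcript sets against simulation ground truth.

The matching identity is the junction chain: a predicted multi-exon
transcript is a true positive iff some truth transcript on the same
chromosome and strand has exactly the same ordered internal exon/exon
junction coordinates — transcription start and end are notoriously hard
to predict and are not required to be correct.  A prediction with at
least one wrong junction is a false positive, and an expressed truth
transcript never matched is a false negative.  Precision and recall are
reported overall and stratified (annotation status, event category,
forms per gene, coverage bin), each with a comfort-zone flag: results
with recall < 25% or precision < 66.6% are questionable for practice.

Single-exon transcripts have no junctions, so they are matched by >= 50%
reciprocal exon overlap instead (threshold configurable).

A quantification block compares inferred FPKM to true FPKM by Pearson
correlation after removing on/off errors (true zero called positive, or
true positive called zero) and extreme outliers, and a base-level
alignment accuracy routine scores any SAM against the perfect truth SAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core import Annotation, Exon, SpliceBenchError, junction_chain
from .variants import TruthAnnotation

if TYPE_CHECKING:  # avoids an import cycle with corrupt
    from .corrupt import CorruptionLedger

log = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    recall_floor: float = 0.25
    precision_floor: float = 2.0 / 3.0
    coverage_bins: Tuple[float, ...] = (1.0, 10.0, 100.0)  # low/medium/high edges
    coverage_bin_names: Tuple[str, ...] = ("low", "medium", "high")
    fn_expression_threshold: int = 1  # min true exonic fragments to demand detection
    outlier_log10_bound: float = 2.0  # |log10(inferred/true)| beyond this is an outlier
    single_exon_overlap: float = 0.5  # reciprocal overlap for single-exon matching

    def __post_init__(self) -> None:
        if not (0 < self.recall_floor < 1 and 0 < self.precision_floor < 1):
            raise ValueError("comfort-zone floors must lie in (0, 1)")
        if list(self.coverage_bins) != sorted(self.coverage_bins):
            raise ValueError("coverage_bins must be ordered")


def single_exon_match(a: Exon, b: Exon, min_reciprocal: float = 0.5) -> bool:
    """>= 50% reciprocal overlap between two single exons (each way)."""
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return overlap >= min_reciprocal * a.length and overlap >= min_reciprocal * b.length


def stratify_by_coverage(
    true_counts: pd.DataFrame, config: EvaluationConfig
) -> Dict[str, Optional[str]]:
    """Assign each expressed transcript its depth-of-coverage bin.

    Bins are half-open upward, [1, 10), [10, 100), [100, inf) by default;
    coverage below the lowest edge is unbinned (excluded from binned
    strata, logged).
    """
    bins: Dict[str, Optional[str]] = {}
    edges = list(config.coverage_bins)
    n_unbinned = 0
    for row in true_counts.itertuples():
        cov = float(row.coverage)
        if cov < edges[0]:
            bins[row.transcript_id] = None
            n_unbinned += 1
            continue
        idx = int(np.searchsorted(np.asarray(edges), cov, side="right")) - 1
        bins[row.transcript_id] = config.coverage_bin_names[idx]
    if n_unbinned:
        log.info("%d transcripts below the lowest coverage bin (unbinned)", n_unbinned)
    return bins


@dataclass
class TranscriptClassification:
    """Outcome of matching a predicted set against truth."""

    predictions: pd.DataFrame  # pred_id, status in {TP, FP, duplicate}, matched_truth
    truth: pd.DataFrame  # truth_id, expressed, detected, labels
    config: EvaluationConfig

    @property
    def n_tp(self) -> int:
        return int((self.predictions["status"] == "TP").sum())

    @property
    def n_fp(self) -> int:
        return int((self.predictions["status"] == "FP").sum())

    @property
    def n_fn(self) -> int:
        t = self.truth
        return int((t["expressed"] & ~t["detected"]).sum())


def _strand_compatible(pred: str, truth: str) -> bool:
    return pred == "." or pred == truth


def classify_predictions(
    predicted: Annotation,
    truth: TruthAnnotation,
    true_counts: pd.DataFrame,
    ledger: Optional[CorruptionLedger],
    config: Optional[EvaluationConfig] = None,
) -> TranscriptClassification:
    """Classify every prediction (TP/FP/duplicate) and every truth form.

    Multiple predictions matching one truth form count as one TP; the
    surplus is deduplicated (neither TP nor FP, logged).  Predictions on
    chromosomes absent from the truth are false positives with a warning.
    Unstranded predictions ('.') match either strand.  Each truth form
    carries stratification labels: annotation status (from the ledger),
    event category, forms per gene and coverage bin.
    """
    config = config or EvaluationConfig()
    counts_by_id = dict(zip(true_counts["transcript_id"], true_counts["fragments"]))
    coverage_bin = stratify_by_coverage(true_counts, config)

    chain_index: Dict[tuple, List[str]] = {}
    single_index: Dict[str, List[Tuple[Exon, str, str]]] = {}
    truth_chroms = set()
    for t in truth.annotation.transcripts():
        truth_chroms.add(t.chrom)
        if len(t.exons) > 1:
            chain = junction_chain(t)
            chain_index.setdefault((t.chrom, chain.junctions), []).append(t.id)
        else:
            single_index.setdefault(t.chrom, []).append((t.exons[0], t.strand, t.id))

    matched_truth: set = set()
    pred_rows = []
    n_dup = 0
    for p in predicted.transcripts():
        if p.chrom not in truth_chroms:
            log.warning("prediction %s on unknown contig %s: false positive", p.id, p.chrom)
            pred_rows.append((p.id, "FP", None))
            continue
        match_id = None
        if len(p.exons) > 1:
            chain = junction_chain(p)
            for tid in chain_index.get((p.chrom, chain.junctions), []):
                if _strand_compatible(p.strand, truth.annotation.transcript(tid).strand):
                    match_id = tid
                    if tid not in matched_truth:
                        break
        else:
            for exon, strand, tid in single_index.get(p.chrom, []):
                if _strand_compatible(p.strand, strand) and single_exon_match(
                    p.exons[0], exon, config.single_exon_overlap
                ):
                    match_id = tid
                    if tid not in matched_truth:
                        break
        if match_id is None:
            pred_rows.append((p.id, "FP", None))
        elif match_id in matched_truth:
            n_dup += 1
            pred_rows.append((p.id, "duplicate", match_id))
        else:
            matched_truth.add(match_id)
            pred_rows.append((p.id, "TP", match_id))
    if n_dup:
        log.info("%d duplicate predictions deduplicated (neither TP nor FP)", n_dup)

    hidden = ledger.hidden_expressed if ledger else set()
    truth_rows = []
    for t in truth.annotation.transcripts():
        frags = int(counts_by_id.get(t.id, 0))
        expressed = frags >= config.fn_expression_threshold
        truth_rows.append(
            (
                t.id,
                expressed,
                t.id in matched_truth,
                "hidden" if t.id in hidden else "annotated_provided",
                truth.category_of_transcript(t.id).value,
                truth.forms_of_transcript(t.id),
                coverage_bin.get(t.id),
            )
        )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["truth_id", "expressed", "detected", "status", "category", "forms", "coverage_bin"],
    )
    pred_df = pd.DataFrame(pred_rows, columns=["pred_id", "status", "matched_truth"])
    cls = TranscriptClassification(pred_df, truth_df, config)
    _attach_fp_strata(cls, predicted, truth, truth_df)
    return cls


def _attach_fp_strata(
    cls: TranscriptClassification,
    predicted: Annotation,
    truth: TruthAnnotation,
    truth_df: pd.DataFrame,
) -> None:
    """Attribute each FP to its best span-overlapping truth gene.

    A false positive has no truth transcript, but stratified precision
    needs FPs placed somewhere: each is assigned the truth gene whose
    genomic span it overlaps most (same chromosome, compatible strand),
    inheriting that gene's category, forms and coverage bin (the bin of
    the gene's best-covered form), with status "hidden" when the gene
    contains hidden transcripts.  Unattributable FPs stay unstratified
    and count only in overall precision.
    """
    by_truth = truth_df.set_index("truth_id")
    gene_spans: Dict[str, List] = {}
    for gene in truth.annotation.genes:
        gene_spans.setdefault(gene.chrom, []).append(gene)

    labels = {"gene": [], "status": [], "category": [], "forms": [], "coverage_bin": []}
    for row in cls.predictions.itertuples():
        if row.status != "FP":
            for key in labels:
                labels[key].append(None)
            continue
        p = predicted.transcript(row.pred_id)
        best, best_ov = None, 0
        for gene in gene_spans.get(p.chrom, []):
            if not _strand_compatible(p.strand, gene.strand):
                continue
            ov = min(p.end, gene.end) - max(p.start, gene.start)
            if ov > best_ov:
                best, best_ov = gene, ov
        if best is None:
            labels["gene"].append(None)
            labels["status"].append(None)
            labels["category"].append(None)
            labels["forms"].append(None)
            labels["coverage_bin"].append(None)
            continue
        member = by_truth.loc[[t.id for t in best.transcripts]]
        bins = [b for b in member["coverage_bin"] if b is not None]
        order = {name: i for i, name in enumerate(cls.config.coverage_bin_names)}
        labels["gene"].append(best.id)
        labels["status"].append("hidden" if (member["status"] == "hidden").any() else "annotated_provided")
        labels["category"].append(member["category"].iloc[0])
        labels["forms"].append(member["forms"].iloc[0])
        labels["coverage_bin"].append(max(bins, key=order.get) if bins else None)
    for key in ("status", "category", "forms", "coverage_bin"):
        cls.predictions[f"fp_{key}"] = labels[key]


def precision_recall(
    tp: int, fp: int, fn: int, config: Optional[EvaluationConfig] = None
) -> Tuple[Optional[float], Optional[float], Optional[bool]]:
    """Precision, recall and the comfort-zone flag for one stratum.

    Undefined ratios (empty denominators) are returned as None, and the
    comfort-zone flag is absent unless both ratios are defined.
    """
    config = config or EvaluationConfig()
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    comfort = None
    if precision is not None and recall is not None:
        comfort = recall >= config.recall_floor and precision >= config.precision_floor
    return precision, recall, comfort


@dataclass
class EvaluationReport:
    strata: pd.DataFrame
    quantification: Optional[dict] = None
    alignment_accuracy: Optional[float] = None
    config: EvaluationConfig = field(default_factory=EvaluationConfig)


def build_report(
    classification: TranscriptClassification,
    config: Optional[EvaluationConfig] = None,
    quantification: Optional[dict] = None,
    alignment_accuracy: Optional[float] = None,
) -> EvaluationReport:
    """Aggregate the classification into per-stratum accuracy rows."""
    config = config or classification.config
    truth = classification.truth
    preds = classification.predictions
    expressed = truth[truth["expressed"]]

    def stratum_row(dim: str, value, truth_mask, fp_mask) -> tuple:
        tp = int((expressed[truth_mask] ["detected"]).sum())
        fn = int((~expressed[truth_mask]["detected"]).sum())
        fp = int(fp_mask.sum())
        p, r, cz = precision_recall(tp, fp, fn, config)
        return (dim, str(value), tp, fp, fn, p, r, cz)

    fp_all = preds["status"] == "FP"
    rows = [stratum_row("overall", "all", np.ones(len(expressed), dtype=bool), fp_all)]
    dims = [
        ("status", "status", "fp_status"),
        ("category", "category", "fp_category"),
        ("forms", "forms", "fp_forms"),
        ("coverage", "coverage_bin", "fp_coverage_bin"),
    ]
    for dim, tcol, pcol in dims:
        values = sorted(
            {v for v in expressed[tcol] if pd.notna(v)}
            | {v for v in preds.loc[fp_all, pcol] if pd.notna(v)},
            key=str,
        )
        for v in values:
            truth_mask = (expressed[tcol] == v).to_numpy()
            fp_mask = fp_all & (preds[pcol] == v)
            rows.append(stratum_row(dim, v, truth_mask, fp_mask))
    strata = pd.DataFrame(
        rows,
        columns=["dimension", "stratum", "tp", "fp", "fn", "precision", "recall", "comfort_zone"],
    )
    return EvaluationReport(strata, quantification, alignment_accuracy, config)


def quantification_agreement(
    true_quant: pd.DataFrame,
    inferred_quant: pd.DataFrame,
    config: Optional[EvaluationConfig] = None,
) -> dict:
    """Pearson agreement between true and inferred FPKM.

    On/off errors (true zero inferred positive, or the reverse) are
    counted and removed; remaining both-positive pairs are filtered by
    the extreme-outlier rule |log10(inferred/true)| > bound (removed
    count reported); Pearson r is computed on the survivors.  Transcripts
    absent from one table are treated as zero there.
    """
    config = config or EvaluationConfig()
    t = true_quant.set_index("transcript_id")["fpkm"]
    i = inferred_quant.set_index("transcript_id")["fpkm"]
    ids = t.index.union(i.index)
    tv = t.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    iv = i.reindex(ids).fillna(0.0).to_numpy(dtype=float)

    false_on = (tv == 0) & (iv > 0)
    false_off = (tv > 0) & (iv == 0)
    both_pos = (tv > 0) & (iv > 0)
    both_zero = (tv == 0) & (iv == 0)

    ratio = np.full(len(ids), np.nan)
    ratio[both_pos] = np.log10(iv[both_pos] / tv[both_pos])
    outlier = both_pos & (np.abs(ratio) > config.outlier_log10_bound)
    surviving = both_pos & ~outlier

    n_surv = int(surviving.sum())
    if n_surv >= 3:
        r = float(stats.pearsonr(tv[surviving], iv[surviving]).statistic)
    else:
        r = None
    return {
        "pearson_r": r,
        "n_both_positive": int(both_pos.sum()),
        "n_both_zero": int(both_zero.sum()),
        "n_false_on": int(false_on.sum()),
        "n_false_off": int(false_off.sum()),
        "n_outliers_removed": int(outlier.sum()),
        "n_surviving": n_surv,
    }


def _aligned_positions(read: pysam.AlignedSegment):
    """Per query position (forward-genomic storage order): refname/pos or None."""
    out: List[Optional[Tuple[str, int]]] = [None] * read.query_length
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if qpos is not None:
            out[qpos] = (read.reference_name, rpos) if rpos is not None else None
    return out


def _mate_key(read: pysam.AlignedSegment) -> tuple:
    return (read.query_name, read.is_read2)


def alignment_base_accuracy(test_sam, truth_sam) -> float:
    """Fraction of truth-aligned bases placed correctly by a test SAM.

    A sequenced base is accurate iff the test alignment places it at the
    same reference coordinate as the perfect truth alignment; unaligned
    or missing reads contribute only inaccurate bases.  Bases the truth
    itself does not align (inserted bases) are excluded from the
    denominator.  A test read absent from the truth is an input error.
    """
    truth: Dict[tuple, tuple] = {}
    denominator = 0
    with pysam.AlignmentFile(str(truth_sam), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            pos = _aligned_positions(read)
            truth[_mate_key(read)] = (pos, read.is_reverse)
            denominator += sum(p is not None for p in pos)
    if denominator == 0:
        raise SpliceBenchError("truth SAM aligns no bases")

    accurate = 0
    with pysam.AlignmentFile(str(test_sam), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            key = _mate_key(read)
            if key not in truth:
                raise SpliceBenchError(
                    f"read {read.query_name} mate{2 if read.is_read2 else 1} "
                    "present in test SAM but absent from truth"
                )
            truth_pos, truth_rev = truth[key]
            test_pos = _aligned_positions(read)
            if read.is_reverse != truth_rev:
                test_pos = test_pos[::-1]
            for tp, xp in zip(truth_pos, test_pos):
                if tp is not None and xp == tp:
                    accurate += 1
    return accurate / denominator


def write_report(report: EvaluationReport, path) -> None:
    """Write the stratified TSV and a human-readable summary.

    ``path`` is a directory; emits report.tsv and summary.txt with
    deterministic bytes for a fixed report.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    strata = report.strata.copy()
    strata = strata.sort_values(["dimension", "stratum"], kind="mergesort").reset_index(drop=True)
    strata.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")

    lines = ["transcript-level accuracy", "=" * 25]
    for row in strata.itertuples():
        p = "NA" if row.precision is None or pd.isna(row.precision) else f"{row.precision:.4f}"
        r = "NA" if row.recall is None or pd.isna(row.recall) else f"{row.recall:.4f}"
        cz = {True: "in", False: "OUT OF", None: "NA"}.get(row.comfort_zone, "NA")
        lines.append(
            f"{row.dimension}={row.stratum}: TP={row.tp} FP={row.fp} FN={row.fn} "
            f"precision={p} recall={r} ({cz} comfort zone)"
        )
    if report.quantification:
        q = report.quantification
        lines.append("")
        lines.append("quantification agreement")
        lines.append("=" * 24)
        r = q["pearson_r"]
        lines.append(f"pearson_r={'NA' if r is None else format(r, '.4f')}")
        for key in ("n_both_positive", "n_false_on", "n_false_off", "n_outliers_removed"):
            lines.append(f"{key}={q[key]}")
    if report.alignment_accuracy is not None:
        lines.append("")
        lines.append(f"alignment_base_accuracy={report.alignment_accuracy:.4f}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
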