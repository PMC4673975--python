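"""Junction-chain scoring, strata, quantification and alignment accuracy."""

import numpy as np
import pandas as pd
import pytest

from splicebench import (
    Annotation,
    EvaluationConfig,
    Gene,
    Transcript,
    TruthAnnotation,
    alignment_base_accuracy,
    build_report,
    classify_predictions,
    junction_chain,
    precision_recall,
    quantification_agreement,
    stratify_by_coverage,
    write_report,
)
from splicebench.evaluate import single_exon_match
from splicebench.core import SpliceBenchError
from conftest import make_transcript


def truth_of(transcripts):
    genes = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return TruthAnnotation.trivial(Annotation([Gene(g, ts) for g, ts in genes.items()]))


def counts_for(truth, fragments=100):
    rows = [
        (t.id, fragments, t.length, 0.0, 2 * 100 * fragments / t.length)
        for t in truth.annotation.transcripts()
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "fragments", "length", "fpkm", "coverage"]
    )


def brute_force_classify(predicted, truth, min_reciprocal=0.5):
    """Independent oracle: exhaustive pairwise comparison with in-order dedup."""
    matched = set()
    statuses = {}
    for p in predicted.transcripts():
        candidates = []
        for t in truth.annotation.transcripts():
            if p.chrom != t.chrom:
                continue
            if p.strand != "." and p.strand != t.strand:
                continue
            if len(p.exons) > 1 and len(t.exons) > 1:
                if junction_chain(p).junctions == junction_chain(t).junctions:
                    candidates.append(t.id)
            elif len(p.exons) == 1 and len(t.exons) == 1:
                if single_exon_match(p.exons[0], t.exons[0], min_reciprocal):
                    candidates.append(t.id)
        fresh = [c for c in candidates if c not in matched]
        if fresh:
            matched.add(fresh[0])
            statuses[p.id] = "TP"
        elif candidates:
            statuses[p.id] = "duplicate"
        else:
            statuses[p.id] = "FP"
    return statuses, matched


def random_instance(rng, n_truth=6):
    """A random truth set plus predictions derived from it by perturbation."""
    truth_txs = []
    cursor = 100
    for i in range(n_truth):
        n_exons = int(rng.integers(1, 5))
        exons, pos = [], cursor
        for _ in range(n_exons):
            ln = int(rng.integers(50, 200))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(30, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        truth_txs.append(
            make_transcript(exons, tx_id=f"t{i}", gene_id=f"g{i}", strand=strand)
        )
        cursor = pos + 300
    truth = truth_of(truth_txs)

    preds = []
    for j in range(int(rng.integers(1, 2 * n_truth))):
        base = truth_txs[int(rng.integers(n_truth))]
        exons = [(e.start, e.end) for e in base.exons]
        kind = rng.random()
        if kind < 0.4:  # terminal perturbation: TP-preserving
            exons[0] = (max(0, exons[0][0] - int(rng.integers(0, 40))), exons[0][1])
            exons[-1] = (exons[-1][0], exons[-1][1] + int(rng.integers(0, 40)))
        elif kind < 0.7 and len(exons) > 1:  # internal junction shift: FP
            k = int(rng.integers(len(exons) - 1))
            exons[k] = (exons[k][0], exons[k][1] - int(rng.integers(1, 10)))
        elif len(exons) == 1:  # slide a single exon
            shift = int(rng.integers(-60, 60))
            exons[0] = (exons[0][0] + shift, exons[0][1] + shift)
        preds.append(
            make_transcript(
                exons, tx_id=f"p{j}", gene_id=f"pg{j}", strand=base.strand
            )
        )
    genes = [Gene(f"pg{j}", [p]) for j, p in enumerate(preds)]
    return truth, Annotation(genes)


class TestClassifyAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(30))
    def test_agreement_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        truth, predicted = random_instance(rng)
        statuses, _ = brute_force_classify(predicted, truth)
        cls = classify_predictions(predicted, truth, counts_for(truth), None)
        got = dict(zip(cls.predictions["pred_id"], cls.predictions["status"]))
        assert got == statuses


class TestClassifyPredictions:
    def setup_truth(self):
        t1 = make_transcript(
            [(100, 200), (300, 400), (500, 600)], tx_id="t1", gene_id="g1"
        )
        t2 = make_transcript([(1000, 1500)], tx_id="t2", gene_id="g2")
        return truth_of([t1, t2])

    def test_terminal_extension_is_tp(self):
        truth = self.setup_truth()
        pred = make_transcript(
            [(50, 200), (300, 400), (500, 650)], tx_id="p1", gene_id="pg"
        )
        cls = classify_predictions(
            Annotation([Gene("pg", [pred])]), truth, counts_for(truth), None
        )
        assert list(cls.predictions["status"]) == ["TP"]

    def test_internal_junction_shift_is_fp(self):
        truth = self.setup_truth()
        pred = make_transcript(
            [(100, 203), (300, 400), (500, 600)], tx_id="p1", gene_id="pg"
        )
        cls = classify_predictions(
            Annotation([Gene("pg", [pred])]), truth, counts_for(truth), None
        )
        assert list(cls.predictions["status"]) == ["FP"]

    def test_single_exon_reciprocal_overlap(self):
        truth = self.setup_truth()
        good = make_transcript([(1100, 1550)], tx_id="p1", gene_id="a")  # 80% both ways
        bad = make_transcript([(1400, 2400)], tx_id="p2", gene_id="b")  # 20%/10%
        cls = classify_predictions(
            Annotation([Gene("a", [good]), Gene("b", [bad])]),
            truth,
            counts_for(truth),
            None,
        )
        got = dict(zip(cls.predictions["pred_id"], cls.predictions["status"]))
        assert got == {"p1": "TP", "p2": "FP"}

    def test_unstranded_prediction_matches_either_strand(self):
        t = make_transcript(
            [(100, 200), (300, 400)], tx_id="t", gene_id="g", strand="-"
        )
        truth = truth_of([t])
        pred = make_transcript(
            [(100, 200), (300, 400)], tx_id="p", gene_id="pg", strand="."
        )
        cls = classify_predictions(
            Annotation([Gene("pg", [pred])]), truth, counts_for(truth), None
        )
        assert list(cls.predictions["status"]) == ["TP"]

    def test_unknown_contig_is_fp(self):
        truth = self.setup_truth()
        pred = make_transcript(
            [(100, 200), (300, 400)], tx_id="p", gene_id="pg", chrom="chrUn"
        )
        cls = classify_predictions(
            Annotation([Gene("pg", [pred])]), truth, counts_for(truth), None
        )
        assert list(cls.predictions["status"]) == ["FP"]

    def test_duplicates_do_not_change_precision(self):
        truth = self.setup_truth()
        p1 = make_transcript([(90, 200), (300, 400), (500, 610)], tx_id="p1", gene_id="a")
        p2 = make_transcript([(80, 200), (300, 400), (500, 620)], tx_id="p2", gene_id="b")
        single = Annotation([Gene("a", [p1])])
        doubled = Annotation([Gene("a", [p1]), Gene("b", [p2])])
        r1 = build_report(classify_predictions(single, truth, counts_for(truth), None))
        r2 = build_report(classify_predictions(doubled, truth, counts_for(truth), None))
        assert (
            r1.strata.iloc[0]["precision"] == r2.strata.iloc[0]["precision"]
        )
        dup = classify_predictions(doubled, truth, counts_for(truth), None)
        assert (dup.predictions["status"] == "duplicate").sum() == 1

    def test_unexpressed_truth_is_never_fn(self):
        truth = self.setup_truth()
        counts = counts_for(truth)
        counts.loc[counts["transcript_id"] == "t2", ["fragments", "coverage"]] = 0
        cls = classify_predictions(Annotation([]), truth, counts, None)
        assert cls.n_fn == 1  # only the expressed t1


class TestPrecisionRecall:
    def test_simple_arithmetic(self):
        p, r, _ = precision_recall(2, 1, 2)
        assert (p, r) == (2 / 3, 0.5)

    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (1, 0, 3, True),  # recall exactly 0.25, precision 1
            (1, 0, 4, False),  # recall 0.2 < floor
            (2, 1, 0, True),  # precision exactly 2/3
            (2, 2, 0, False),  # precision 0.5 < floor
        ],
    )
    def test_comfort_zone_flips_at_the_floors(self, tp, fp, fn, expected):
        assert precision_recall(tp, fp, fn)[2] is expected

    def test_degenerate_counts_marked_undefined(self):
        p, r, cz = precision_recall(0, 0, 5)
        assert p is None and r == 0 and cz is None


class TestCoverageStrata:
    def test_bin_edges(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c", "d"],
                "fragments": [1] * 4,
                "coverage": [10.0, 0.5, 1e6, 1.0],
            }
        )
        bins = stratify_by_coverage(df, EvaluationConfig())
        assert bins == {"a": "medium", "b": None, "c": "high", "d": "low"}


class TestQuantification:
    def test_identity_gives_r1_no_onoff(self):
        q = pd.DataFrame({"transcript_id": ["a", "b", "c"], "fpkm": [1.0, 5.0, 9.0]})
        block = quantification_agreement(q, q.copy())
        assert block["pearson_r"] == pytest.approx(1.0)
        assert block["n_false_on"] == block["n_false_off"] == 0

    def test_hand_counted_onoff_split(self):
        true = pd.DataFrame({"transcript_id": list("abc"), "fpkm": [0.0, 5.0, 5.0]})
        inferred = pd.DataFrame({"transcript_id": list("abc"), "fpkm": [2.0, 0.0, 5.0]})
        block = quantification_agreement(true, inferred)
        assert block["n_false_on"] == 1
        assert block["n_false_off"] == 1
        assert block["n_both_positive"] == 1
        assert block["pearson_r"] is None  # < 3 surviving pairs

    def test_scaling_preserves_correlation(self):
        true = pd.DataFrame({"transcript_id": list("abcd"), "fpkm": [1.0, 2.0, 4.0, 9.0]})
        inferred = true.copy()
        inferred["fpkm"] = 2 * inferred["fpkm"]
        assert quantification_agreement(true, inferred)["pearson_r"] == pytest.approx(1.0)

    def test_outlier_removal_is_reported(self):
        true = pd.DataFrame({"transcript_id": list("abcd"), "fpkm": [1.0, 2.0, 4.0, 1.0]})
        inferred = true.copy()
        inferred.loc[3, "fpkm"] = 500.0  # |log10(500)| > 2
        block = quantification_agreement(true, inferred)
        assert block["n_outliers_removed"] == 1
        assert block["n_surviving"] == 3

    def test_classification_conservation(self):
        rng = np.random.default_rng(0)
        ids = [f"t{i}" for i in range(50)]
        tv = rng.choice([0.0, 1.0, 5.0], size=50)
        iv = rng.choice([0.0, 2.0, 8.0], size=50)
        block = quantification_agreement(
            pd.DataFrame({"transcript_id": ids, "fpkm": tv}),
            pd.DataFrame({"transcript_id": ids, "fpkm": iv}),
        )
        total = (
            block["n_false_on"]
            + block["n_false_off"]
            + block["n_both_positive"]
            + block["n_both_zero"]
        )
        assert total == 50


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def sam_pair_lines(name, pos1, pos2, seq="A" * 100):
    q = "I" * len(seq)
    return (
        f"{name}\t99\tchr1\t{pos1}\t60\t100M\t=\t{pos2}\t{pos2 - pos1 + 100}\t{seq}\t{q}\n"
        f"{name}\t147\tchr1\t{pos2}\t60\t100M\t=\t{pos1}\t{-(pos2 - pos1 + 100)}\t{seq}\t{q}\n"
    )


class TestAlignmentAccuracy:
    def write(self, path, body):
        path.write_text(SAM_HEADER + body)
        return path

    def test_identity_is_one(self, tmp_path):
        body = "".join(sam_pair_lines(f"seq.{k}", 100 + 500 * k, 400 + 500 * k) for k in range(10))
        truth = self.write(tmp_path / "truth.sam", body)
        assert alignment_base_accuracy(truth, truth) == 1.0

    def test_one_shifted_mate_hand_count(self, tmp_path):
        pairs = [(f"seq.{k}", 100 + 500 * k, 400 + 500 * k) for k in range(10)]
        truth = self.write(
            tmp_path / "truth.sam", "".join(sam_pair_lines(*p) for p in pairs)
        )
        shifted = pairs.copy()
        shifted[0] = (pairs[0][0], pairs[0][1] + 1, pairs[0][2])  # one mate off by 1
        test = self.write(
            tmp_path / "test.sam", "".join(sam_pair_lines(*p) for p in shifted)
        )
        # 10 pairs x 2 mates x 100 bases; one 100-base mate fully misplaced
        assert alignment_base_accuracy(test, truth) == pytest.approx(1900 / 2000)

    def test_empty_test_sam_is_zero(self, tmp_path):
        truth = self.write(
            tmp_path / "truth.sam", sam_pair_lines("seq.1", 100, 400)
        )
        test = self.write(tmp_path / "empty.sam", "")
        assert alignment_base_accuracy(test, truth) == 0.0

    def test_unknown_read_is_input_error(self, tmp_path):
        truth = self.write(tmp_path / "truth.sam", sam_pair_lines("seq.1", 100, 400))
        test = self.write(tmp_path / "test.sam", sam_pair_lines("rogue.1", 100, 400))
        with pytest.raises(SpliceBenchError, match="rogue.1"):
            alignment_base_accuracy(test, truth)


class TestWriteReport:
    def test_deterministic_bytes_and_shape(self, tmp_path):
        truth = truth_of(
            [make_transcript([(100, 200), (300, 400)], tx_id="t", gene_id="g")]
        )
        cls = classify_predictions(
            truth.annotation, truth, counts_for(truth), None
        )
        report = build_report(cls)
        write_report(report, tmp_path / "r1")
        write_report(report, tmp_path / "r2")
        assert (tmp_path / "r1/report.tsv").read_bytes() == (
            tmp_path / "r2/report.tsv"
        ).read_bytes()
        lines = (tmp_path / "r1/report.tsv").read_text().splitlines()
        assert lines[0].startswith("dimension\tstratum")
        assert len(lines) >= 2
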