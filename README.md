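# splicebench

A benchmarking toolkit for full-length transcript reconstruction from
RNA-Seq. Transcript assemblers (Cufflinks, StringTie, CLASS, de novo
assemblers mapped back with GMAP, ...) emit transcript models as GTF and
often per-transcript abundances; judging them requires data whose true
transcript models and true expression are known exactly. splicebench
provides the whole loop with no downloads:

* **synthetic genomes and gene sets** — i.i.d.-base chromosomes carrying
  non-overlapping, single-transcript genes drawn from configurable
  exon-count/length laws;
* **systematic truth sets** — genes labeled with exactly one category of
  alternative processing (exon skipping, truncation of the transcript
  start/end, or splice-site shifts, the shifts mostly by multiples of
  three) at controlled splice-form counts, never mixing categories within
  a gene, so accuracy can be isolated per event type;
* **read simulation** — strand-specific paired-end reads with a
  truncated-normal fragment-length law, optional sequencing error,
  genomic polymorphisms (substitutions and small indels) and intron
  signal from unspliced pre-mRNA, plus a *perfect truth alignment* (SAM
  against the reference, with N/I/D CIGAR operations), a per-read-pair
  truth table and true per-transcript FPKM;
* **annotation corruption** — hides a chosen fraction of the expressed
  transcripts and optionally plants unexpressed decoy models of the same
  genes, emulating the imperfect annotation given to guided assemblers;
* **evaluation** — junction-chain matching with precision/recall per
  stratum, comfort-zone flags, FPKM agreement and base-level alignment
  accuracy.

## The metrics

A transcript's identity for matching is its **junction chain**: the
ordered internal exon/exon boundary pairs. A predicted multi-exon model
is a **true positive** iff some truth model on the same chromosome and
strand has an identical chain — transcription start/end coordinates are
notoriously hard to infer and are not required to be correct. A model
with at least one wrong junction is a **false positive**; an expressed
truth model never matched is a **false negative**. Then

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

and a result with recall < 25% or precision < 66.6% falls outside the
**comfort zone** where error rates become questionable for practice.
Single-exon models (empty chain) match by ≥ 50% reciprocal exon overlap.
True expression is quantified as

    FPKM_t = C_t / ((L_t / 10^3) · (N / 10^6))

from the actually simulated exonic fragment counts C_t (intron-signal
fragments never count), and inferred FPKM is compared to it by Pearson
correlation after removing on/off errors and extreme outliers
(|log10 ratio| > 2).

## Worked example

```
splicebench make-fixture --n-genes 30 --seed 1 --out fx
splicebench design-t1 --annotation fx/base_annotation.gtf --design design.yaml --seed 1 --out t1
splicebench simulate --genome fx/genome.fa --truth t1/truth.gtf \
    --categories t1/truth_categories.tsv --seed 1 --out sim
splicebench corrupt --truth t1/truth.gtf --categories t1/truth_categories.tsv \
    --profile sim/expression_profile.tsv --hide-fraction 0.4 --seed 1 --out prov
splicebench evaluate --truth t1/truth.gtf --categories t1/truth_categories.tsv \
    --truth-quant sim/truth_quant.tsv --ledger prov/corruption_ledger.tsv \
    --pred prov/provided_annotation.gtf --out eval
```

with a small `design.yaml` (4 single-form genes, plus per category 2
genes at 2 forms and 2 at 3 forms) this prints, in order:

```
16 genes, 34 transcripts
7837 fragments (0 intron-signal, 30 dropped short)
hidden 14, planted 14, retained 20
overall: TP=20 FP=14 FN=13 precision=0.588 recall=0.606
```

and `eval/summary.txt` contains, among other strata:

```
status=annotated_provided: TP=20 FP=0 FN=0 precision=1.0000 recall=1.0000 (in comfort zone)
status=hidden: TP=0 FP=14 FN=13 precision=0.0000 recall=0.0000 (OUT OF comfort zone)
```

which reads as: feeding the *corrupted* annotation back as "predictions"
recovers every retained model perfectly, every planted decoy is a false
positive, and every hidden expressed model is a false negative (13 of
the 14 hidden forms received fragments; one short truncation variant
drew none and is therefore not demanded). This closure is the toolkit's
own self-check — a real assembler's GTF (and optional FPKM TSV via
`--pred-quant`, and its alignment via `--test-sam`/`--truth-sam`) slots
into the same `evaluate` call.

The same API is available as a library (`splicebench.simulate_dataset`,
`splicebench.classify_predictions`, ...); every output is a plain text
file (FASTA/GTF/SAM/FASTQ/TSV/YAML/JSON) and every subcommand writes a
manifest that, together with `--seed`, reproduces it byte for byte.

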