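"""Readers and writers for FASTA and GTF/GFF3 annotation files.

GTF coordinates are 1-based inclusive on disk and converted to the
internal 0-based half-open convention at this boundary (the single
conversion site in the package).  Only ``exon`` features are consumed and
emitted: assemblers exchange transcript models as exon chains, and CDS/UTR
features play no role in junction-chain scoring.
"""

from __future__ import annotations

import logging
from collections import OrderedDict, defaultdict
from pathlib import Path
from typing import Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Annotation,
    Exon,
    FormatError,
    Gene,
    Genome,
    Transcript,
    ValidationError,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`, uppercasing sequences.

    Raises :class:`FormatError` naming the offending line for files that
    do not start with a header record.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                )
            break
        else:
            raise FormatError(f"{path}: empty file, no FASTA records")

    sequences: "OrderedDict[str, str]" = OrderedDict()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    genome = Genome(dict(sequences))
    genome.validate_alphabet()
    return genome


def write_fasta(genome: Genome, path: PathLike, width: int = 70) -> None:
    """Write a :class:`Genome` as FASTA with fixed line width."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def _annotation_from_exon_tuples(exon_rows, source: str) -> Annotation:
    """Group (chrom, start0, end0, strand, gene_id, transcript_id) rows."""
    tx_exons: "defaultdict[str, list]" = defaultdict(list)
    tx_meta = {}
    gene_order: "OrderedDict[str, list]" = OrderedDict()
    for chrom, start, end, strand, gene_id, tx_id in exon_rows:
        tx_exons[tx_id].append(Exon(start, end))
        meta = (chrom, strand, gene_id)
        if tx_id in tx_meta and tx_meta[tx_id] != meta:
            raise FormatError(
                f"{source}: transcript {tx_id!r} has inconsistent "
                f"chrom/strand/gene_id across exon records"
            )
        if tx_id not in tx_meta:
            tx_meta[tx_id] = meta
            gene_order.setdefault(gene_id, []).append(tx_id)

    genes = []
    for gene_id, tx_ids in gene_order.items():
        transcripts = []
        for tx_id in tx_ids:
            chrom, strand, _ = tx_meta[tx_id]
            exons = tuple(sorted(tx_exons[tx_id], key=lambda e: (e.start, e.end)))
            try:
                transcripts.append(Transcript(tx_id, gene_id, chrom, strand, exons))
            except ValidationError as exc:
                raise ValidationError(f"{source}: transcript {tx_id!r}: {exc}") from exc
        genes.append(Gene(gene_id, transcripts))
    return Annotation(genes)


def _read_with_gffutils(path: PathLike, dialect: str) -> Annotation:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if dialect == "gtf":
            tx_ids = feat.attributes.get("transcript_id")
            gene_ids = feat.attributes.get("gene_id")
            if not tx_ids:
                raise FormatError(
                    f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                    "lacks a transcript_id attribute"
                )
            tx_id = tx_ids[0]
            gene_id = gene_ids[0] if gene_ids else tx_id
        else:  # GFF3: Parent -> transcript; transcript's Parent -> gene
            parents = feat.attributes.get("Parent")
            if not parents:
                raise FormatError(
                    f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                    "lacks a Parent attribute"
                )
            tx_id = parents[0]
            try:
                tx_feat = db[tx_id]
                gene_id = tx_feat.attributes.get("Parent", [tx_id])[0]
            except gffutils.FeatureNotFoundError:
                gene_id = tx_id
        # gffutils keeps 1-based inclusive GFF coordinates
        rows.append((feat.seqid, feat.start - 1, feat.end, feat.strand, gene_id, tx_id))
    seen_tx = {r[5] for r in rows}
    tx_types = ("transcript", "mRNA")
    for tx_type in tx_types:
        for feat in db.features_of_type(tx_type):
            tid = (
                feat.attributes.get("transcript_id", [feat.id])[0]
                if dialect == "gtf"
                else feat.id
            )
            if tid not in seen_tx:
                log.warning("%s: transcript %s has no exon features; dropped", path, tid)
    return _annotation_from_exon_tuples(rows, str(path))


def read_gtf(path: PathLike) -> Annotation:
    """Read a GTF2.2 file (exon features only) into an :class:`Annotation`.

    Transcripts that have no exon features (e.g. bare ``transcript`` rows)
    are dropped with a logged warning, matching assembler output handling.
    """
    return _read_with_gffutils(path, "gtf")


def read_gff3(path: PathLike) -> Annotation:
    """Read a GFF3 file via the ID/Parent attribute mapping.

    Thin shim over the GTF reader: Parent of an exon is the transcript id
    and the transcript's Parent is the gene id.  Output is always GTF.
    """
    return _read_with_gffutils(path, "gff3")


def write_gtf(annotation: Annotation, path: PathLike, source: str = "splicebench") -> None:
    """Write exon features in 1-based inclusive GTF, sorted by chrom/start.

    Byte output is deterministic for a fixed annotation.
    """
    records = []
    for gene in annotation.genes:
        for t in gene.transcripts:
            for e in t.exons:
                records.append((t.chrom, e.start, e.end, t.strand, gene.id, t.id))
    records.sort(key=lambda r: (r[0], r[1], r[2], r[5]))
    with open(path, "w") as handle:
        handle.write("##provider: splicebench\n")
        for chrom, start, end, strand, gene_id, tx_id in records:
            attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            handle.write(
                f"{chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
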