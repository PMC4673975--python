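"""Strand-specific paired-end read simulation with perfect truth output.

Fragments are drawn with replacement from transcripts in proportion to
molecule weight, fragment lengths follow a truncated normal, and each
fragment yields one mate pair: mate 1 is the first ``read_length`` bases
of the fragment on the transcript strand, mate 2 the reverse complement
of the last (a forward-stranded protocol by default).  Optional noise:

* polymorphisms — per-base substitutions and small indels are applied to
  the genome once, before any fragment is drawn; reads are then extracted
  from the polymorphic haplotype while the truth alignment is expressed
  against the *reference* through a coordinate map (CIGAR I/D at indels,
  N across introns);
* sequencing error — per sequenced base, a uniform substitution;
* intron signal — with a configurable per-fragment probability the
  fragment is drawn from the unspliced pre-mRNA span of its source
  transcript instead of the mature molecule, emulating the pervasive
  low-coverage signal seen across introns in real libraries.

Alongside the FASTQ pair the simulator emits a perfect SAM alignment, a
per-pair truth table, and per-transcript true counts/FPKM, so aligner and
assembler outputs can be scored with no information loss.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import Annotation, Genome, SpliceBenchError, Transcript
from .rng import substream
from .variants import TruthAnnotation

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class UniformCoverage:
    """All transcripts expressed at the same per-base depth."""

    target_coverage: float = 40.0


@dataclass
class Exponential:
    """A realistic expression spectrum.

    Each transcript is expressed independently with probability
    ``expressed_fraction``; expressed transcripts receive a molecule
    weight drawn from Exponential(rate) (mean 1/rate), others weight 0.
    """

    rate: float = 0.01
    expressed_fraction: float = 2.0 / 3.0


ExpressionModel = Union[UniformCoverage, Exponential]


@dataclass
class SimulationConfig:
    """All simulator parameters.

    Defaults are the clean, maximally idealised setting: 100-base mates,
    fragments 200-500 with median 300 and truncated-normal sd 1000/3, and
    all error, polymorphism and intron rates zero.  The realistic setting
    raises them to basewise_error=0.005, substitution_frequency=0.001,
    indel_frequency=0.0005, intron_frequency=0.3.
    """

    read_length: int = 100
    frag_min: int = 200
    frag_max: int = 500
    frag_median: int = 300
    frag_sd: float = 1000.0 / 3.0
    basewise_error: float = 0.0
    substitution_frequency: float = 0.0
    indel_frequency: float = 0.0
    intron_frequency: float = 0.0
    n_fragments: Optional[int] = None  # solved from coverage when None
    expression_model: ExpressionModel = field(default_factory=UniformCoverage)
    orientation: str = "FR"  # mate 1 on the transcript strand
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frag_min <= self.frag_median <= self.frag_max):
            raise ValueError("need frag_min <= frag_median <= frag_max")
        if self.read_length > self.frag_min:
            raise ValueError("read_length must not exceed frag_min")
        for name in (
            "basewise_error",
            "substitution_frequency",
            "indel_frequency",
            "intron_frequency",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.orientation not in ("FR", "RF"):
            raise ValueError("orientation must be FR or RF")

    @classmethod
    def realistic(cls, **kwargs) -> "SimulationConfig":
        defaults = dict(
            basewise_error=0.005,
            substitution_frequency=0.001,
            indel_frequency=0.0005,
            intron_frequency=0.3,
            expression_model=Exponential(),
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        model = d.pop("expression_model")
        d["expression_model"] = {
            "kind": type(model).__name__,
            **{k: float(v) for k, v in model.__dict__.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        m = d.pop("expression_model")
        kind = m.pop("kind")
        d["expression_model"] = {"UniformCoverage": UniformCoverage, "Exponential": Exponential}[
            kind
        ](**m)
        return cls(**d)


# ---------------------------------------------------------------------------
# expression


ExpressionProfile = Dict[str, float]


def assign_expression(
    truth: TruthAnnotation, model: ExpressionModel, seed: int
) -> ExpressionProfile:
    """Map transcript id -> nonnegative molecule weight.

    Under :class:`UniformCoverage` weight is proportional to spliced
    length, so expected per-base depth is equal across transcripts.
    Under :class:`Exponential` each transcript is independently expressed
    with the configured probability and weighted exponentially.
    """
    rng = substream(seed, "expression")
    tx = list(truth.annotation.transcripts())
    if not tx:
        raise SpliceBenchError("truth annotation is empty")
    if isinstance(model, UniformCoverage):
        return {t.id: float(t.length) for t in tx}
    expressed = rng.random(len(tx)) < model.expressed_fraction
    weights = rng.exponential(scale=1.0 / model.rate, size=len(tx))
    return {t.id: (float(w) if e else 0.0) for t, e, w in zip(tx, expressed, weights)}


def solve_n_fragments(profile: ExpressionProfile, truth: TruthAnnotation, config: SimulationConfig) -> int:
    """Fragment count needed to hit the uniform coverage target.

    Each fragment sequences two mates of ``read_length`` bases, so the
    count solves target * sum(L_t) = 2 * read_length * n.
    """
    if config.n_fragments is not None:
        return config.n_fragments
    if not isinstance(config.expression_model, UniformCoverage):
        raise SpliceBenchError("n_fragments must be given for non-uniform models")
    total_len = sum(
        truth.annotation.transcript(t).length for t, w in profile.items() if w > 0
    )
    target = config.expression_model.target_coverage
    return math.ceil(target * total_len / (2 * config.read_length))


# ---------------------------------------------------------------------------
# polymorphisms and the reference <-> polymorphic coordinate map


@dataclass
class Variant:
    chrom: str
    ref_pos: int
    kind: str  # "sub" | "ins" | "del"
    ref_allele: str
    alt_allele: str


class ChromosomeMap:
    """Monotone piecewise map between polymorphic and reference coordinates.

    Stored as ordered segments (op, ref_start, ref_len, poly_start,
    poly_len) with op M (lengths equal), D (deleted from the polymorphic
    haplotype) or I (inserted into it).
    """

    def __init__(self, segments: List[Tuple[str, int, int, int, int]]):
        self.segments = segments
        self._ref_starts = [s[1] for s in segments]

    @classmethod
    def identity(cls, length: int) -> "ChromosomeMap":
        return cls([("M", 0, length, 0, length)])

    def project(self, ref_start: int, ref_end: int):
        """Project a reference interval into the polymorphic haplotype.

        Returns (poly_start, ops) where ops is a list of (op, ref_len,
        poly_len) covering the interval; insertions anchored strictly
        inside the interval are included.
        """
        i = bisect.bisect_right(self._ref_starts, ref_start) - 1
        i = max(i, 0)
        # back up over I segments anchored exactly at ref_start
        while i > 0 and self.segments[i - 1][1] + self.segments[i - 1][2] > ref_start:
            i -= 1
        ops: List[Tuple[str, int, int]] = []
        poly_start = None
        while i < len(self.segments):
            op, rs, rl, ps, pl = self.segments[i]
            if rs >= ref_end and not (op == "I" and rs < ref_end):
                break
            if op == "I":
                # include only insertions strictly inside the interval
                if ref_start < rs < ref_end:
                    if poly_start is None:
                        poly_start = ps
                    ops.append(("I", 0, pl))
            else:
                lo = max(rs, ref_start)
                hi = min(rs + rl, ref_end)
                if lo < hi:
                    if poly_start is None:
                        poly_start = ps + (lo - rs) if op == "M" else ps
                    ops.append((op, hi - lo, hi - lo if op == "M" else 0))
            i += 1
        if poly_start is None:  # interval fully deleted or empty
            poly_start = self.to_poly(ref_start)
        return poly_start, _merge_ops(ops)

    def to_poly(self, ref_pos: int) -> int:
        """Polymorphic coordinate of the first surviving base at >= ref_pos."""
        for op, rs, rl, ps, pl in self.segments:
            if op == "M" and rs + rl > ref_pos:
                return ps + max(ref_pos - rs, 0)
        last = self.segments[-1]
        return last[3] + last[4]

    def to_ref(self, poly_pos: int) -> int:
        """Reference coordinate of a polymorphic-haplotype base.

        Inserted bases map to the reference position they precede.
        """
        for op, rs, rl, ps, pl in self.segments:
            if pl and ps + pl > poly_pos:
                return rs + (poly_pos - ps) if op == "M" else rs
        last = self.segments[-1]
        return last[1] + last[2]


def _merge_ops(ops: List[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    merged: List[Tuple[str, int, int]] = []
    for op in ops:
        if merged and merged[-1][0] == op[0]:
            prev = merged[-1]
            merged[-1] = (op[0], prev[1] + op[1], prev[2] + op[2])
        else:
            merged.append(op)
    return merged


class CoordinateMap:
    """Per-chromosome :class:`ChromosomeMap` collection."""

    def __init__(self, chrom_maps: Dict[str, ChromosomeMap]):
        self.chrom_maps = chrom_maps

    @classmethod
    def identity(cls, genome: Genome) -> "CoordinateMap":
        return cls({c: ChromosomeMap.identity(n) for c, n in genome.lengths.items()})

    def __getitem__(self, chrom: str) -> ChromosomeMap:
        return self.chrom_maps[chrom]


_BASE_SET = "ACGT"
_ALT = {b: _BASE_SET.replace(b, "") for b in _BASE_SET}


def apply_polymorphisms(
    genome: Genome,
    substitution_frequency: float,
    indel_frequency: float,
    seed: int,
) -> Tuple[Genome, CoordinateMap, List[Variant]]:
    """Plant substitutions and small indels into a reference genome.

    Each base is substituted independently (to a uniformly chosen
    different base); indel events are seeded per base, each an insertion
    or a deletion with equal odds and length uniform on {1, 2, 3}.
    Returns the polymorphic haplotype, the coordinate map back to the
    reference, and the variant list.
    """
    rng = substream(seed, "polymorphisms")
    variants: List[Variant] = []
    new_seqs: Dict[str, str] = {}
    chrom_maps: Dict[str, ChromosomeMap] = {}
    for chrom in genome.sequences:
        seq = genome[chrom]
        n = len(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()

        if substitution_frequency > 0:
            hits = np.flatnonzero(rng.random(n) < substitution_frequency)
            for pos in hits:
                ref_base = arr[pos].decode()
                if ref_base == "N":
                    continue
                alt = _ALT[ref_base][rng.integers(3)]
                arr[pos] = alt.encode()
                variants.append(Variant(chrom, int(pos), "sub", ref_base, alt))
        sub_seq = arr.tobytes().decode("ascii")

        segments: List[Tuple[str, int, int, int, int]] = []
        pieces: List[str] = []
        if indel_frequency > 0:
            sites = np.flatnonzero(rng.random(n) < indel_frequency)
        else:
            sites = np.empty(0, dtype=int)
        ref_cursor = 0
        poly_cursor = 0
        for pos in sites:
            pos = int(pos)
            if pos < ref_cursor:  # swallowed by a previous deletion
                continue
            length = int(rng.integers(1, 4))
            is_ins = rng.random() < 0.5
            if pos > ref_cursor:
                span = pos - ref_cursor
                segments.append(("M", ref_cursor, span, poly_cursor, span))
                pieces.append(sub_seq[ref_cursor:pos])
                poly_cursor += span
                ref_cursor = pos
            if is_ins:
                ins = "".join(_BASE_SET[i] for i in rng.integers(0, 4, size=length))
                segments.append(("I", ref_cursor, 0, poly_cursor, length))
                pieces.append(ins)
                poly_cursor += length
                variants.append(Variant(chrom, ref_cursor, "ins", "", ins))
            else:
                length = min(length, n - ref_cursor)
                if length == 0:
                    continue
                segments.append(("D", ref_cursor, length, poly_cursor, 0))
                variants.append(
                    Variant(chrom, ref_cursor, "del", seq[ref_cursor : ref_cursor + length], "")
                )
                ref_cursor += length
        if ref_cursor < n:
            span = n - ref_cursor
            segments.append(("M", ref_cursor, span, poly_cursor, span))
            pieces.append(sub_seq[ref_cursor:])
        if not segments:
            segments = [("M", 0, n, 0, n)]
            pieces = [sub_seq]
        new_seqs[chrom] = "".join(pieces)
        chrom_maps[chrom] = ChromosomeMap(segments)
    return Genome(new_seqs), CoordinateMap(chrom_maps), variants


# ---------------------------------------------------------------------------
# fragment lengths


def draw_fragment_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    """One truncated-normal draw, rejected until inside [frag_min, frag_max]."""
    while True:
        x = int(round(rng.normal(config.frag_median, config.frag_sd)))
        if config.frag_min <= x <= config.frag_max:
            return x


# ---------------------------------------------------------------------------
# molecule layouts: molecule offset -> reference CIGAR


class MoleculeLayout:
    """Alignment chain of a molecule against the reference genome.

    ``ops`` is a list of (op, ref_len, mol_len) with op in M/I/D/N; M and
    I consume molecule bases, M, D and N consume reference bases.  ``seq``
    is the molecule sequence in genomic (ascending-coordinate)
    orientation, taken from the polymorphic haplotype.
    """

    def __init__(self, chrom: str, ref_start: int, ops, seq: str):
        self.chrom = chrom
        self.ref_start = ref_start
        self.ops = ops
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    def slice_alignment(self, mol_start: int, mol_end: int):
        """CIGAR tuples + reference position for molecule slice [s, e).

        Leading/trailing non-consuming ops (D, N) are trimmed; the CIGAR
        is returned as pysam (op_code, length) tuples.
        """
        cig: List[Tuple[int, int]] = []
        ref = self.ref_start
        mol = 0
        pos = None
        for op, ref_len, mol_len in self.ops:
            if mol >= mol_end and mol_len > 0:
                break
            if mol_len > 0:
                lo = max(mol, mol_start)
                hi = min(mol + mol_len, mol_end)
                if lo < hi:
                    if op == "M":
                        if pos is None:
                            pos = ref + (lo - mol)
                        cig.append((0, hi - lo))
                    else:  # I
                        if pos is None:
                            # slice starts inside an insertion; anchor just after
                            pos = ref
                        cig.append((1, hi - lo))
            else:  # D or N consume reference only
                if mol_start < mol <= mol_end and pos is not None and mol < mol_end:
                    cig.append((2 if op == "D" else 3, ref_len))
            ref += ref_len
            mol += mol_len
        # trim trailing D/N
        while cig and cig[-1][0] in (2, 3):
            cig.pop()
        return pos, _merge_cigar(cig)


def _merge_cigar(cig: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for op, ln in cig:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def spliced_layout(
    transcript: Transcript, poly_genome: Genome, coord_map: CoordinateMap
) -> MoleculeLayout:
    """Layout of the mature (spliced) molecule."""
    cmap = coord_map[transcript.chrom]
    ops: List[Tuple[str, int, int]] = []
    seqs: List[str] = []
    prev_end = None
    ref_start = None
    for exon in transcript.exons:
        if prev_end is not None:
            ops.append(("N", exon.start - prev_end, 0))
        p0, exon_ops = cmap.project(exon.start, exon.end)
        mol_len = sum(pl for _, _, pl in exon_ops)
        seqs.append(poly_genome[transcript.chrom][p0 : p0 + mol_len])
        if ref_start is None:
            first_m = next((o for o in exon_ops if o[0] == "M"), None)
            ref_start = exon.start if first_m else exon.start
        ops.extend(exon_ops)
        prev_end = exon.end
    ops = _merge_ops(ops)
    return MoleculeLayout(transcript.chrom, transcript.exons[0].start, ops, "".join(seqs))


def premrna_layout(
    transcript: Transcript, poly_genome: Genome, coord_map: CoordinateMap
) -> MoleculeLayout:
    """Layout of the unspliced pre-mRNA span (terminal to terminal)."""
    cmap = coord_map[transcript.chrom]
    p0, ops = cmap.project(transcript.start, transcript.end)
    mol_len = sum(pl for _, _, pl in ops)
    seq = poly_genome[transcript.chrom][p0 : p0 + mol_len]
    return MoleculeLayout(transcript.chrom, transcript.start, ops, seq)


# ---------------------------------------------------------------------------
# dataset simulation


@dataclass
class SimulationResult:
    """In-memory truth emitted alongside the on-disk files."""

    truth_table: pd.DataFrame
    true_counts: pd.DataFrame
    n_dropped_short: int
    n_intronic: int
    variants: List[Variant]
    paths: Dict[str, Path]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        base = chars[i]
        chars[i] = _ALT.get(base, "ACG")[rng.integers(3)]
    return "".join(chars)


def simulate_dataset(
    genome: Genome,
    truth: TruthAnnotation,
    profile: ExpressionProfile,
    config: SimulationConfig,
    outdir,
) -> SimulationResult:
    """Simulate a full dataset into ``outdir``.

    Writes reads_1.fastq / reads_2.fastq, truth.sam (coordinate-sorted,
    against the reference), truth_table.tsv (per-pair provenance) and
    truth_quant.tsv (per-transcript fragments, FPKM, mean coverage).
    Molecules shorter than ``frag_min`` contribute no fragments; such
    draws are dropped and counted (short genes are under-represented by
    the fragment-length law, as intended).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = substream(config.seed, "fragments")

    poly_genome, coord_map, variant_list = apply_polymorphisms(
        genome, config.substitution_frequency, config.indel_frequency, config.seed
    )

    transcripts = [
        truth.annotation.transcript(t) for t, w in profile.items() if w > 0
    ]
    if not transcripts:
        raise SpliceBenchError("no transcript has positive expression weight")
    weights = np.array([profile[t.id] for t in transcripts], dtype=float)
    n_fragments = solve_n_fragments(profile, truth, config)

    usable = [t.length >= config.frag_min for t in transcripts]
    if not any(usable):
        raise SpliceBenchError(
            f"no expressed transcript is at least frag_min={config.frag_min} bases"
        )

    picks = rng.choice(len(transcripts), size=n_fragments, p=weights / weights.sum())
    intron_draws = (
        rng.random(n_fragments) < config.intron_frequency
        if config.intron_frequency > 0
        else np.zeros(n_fragments, dtype=bool)
    )

    spliced_cache: Dict[str, MoleculeLayout] = {}
    premrna_cache: Dict[str, MoleculeLayout] = {}

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in genome.lengths.items()],
    }
    sam_header = pysam.AlignmentHeader.from_dict(header)
    tid_of = {c: i for i, c in enumerate(genome.lengths)}

    rl = config.read_length
    qual = pysam.qualitystring_to_array("I" * rl)
    fq1_path, fq2_path = outdir / "reads_1.fastq", outdir / "reads_2.fastq"
    sam_path = outdir / "truth.sam"

    exonic_counts: Dict[str, int] = {t.id: 0 for t in transcripts}
    intronic_counts: Dict[str, int] = {t.id: 0 for t in transcripts}
    table_rows = []
    sam_records = []
    n_dropped = 0
    n_intronic = 0
    k = 0

    fq1 = open(fq1_path, "w")
    fq2 = open(fq2_path, "w")
    try:
        for pick, intronic in zip(picks, intron_draws):
            t = transcripts[pick]
            if intronic and len(t.exons) > 1:
                layout = premrna_cache.get(t.id)
                if layout is None:
                    layout = premrna_layout(t, poly_genome, coord_map)
                    premrna_cache[t.id] = layout
                is_intron_fragment = True
            else:
                layout = spliced_cache.get(t.id)
                if layout is None:
                    layout = spliced_layout(t, poly_genome, coord_map)
                    spliced_cache[t.id] = layout
                is_intron_fragment = False
            mol_len = len(layout)
            if mol_len < config.frag_min:
                n_dropped += 1
                continue
            flen = draw_fragment_length(config, rng)
            while flen > mol_len:
                flen = draw_fragment_length(config, rng)
            # position uniform on the molecule in transcript orientation
            tstart = int(rng.integers(0, mol_len - flen + 1))
            if t.strand == "+":
                gstart = tstart
            else:
                gstart = mol_len - tstart - flen
            frag = layout.seq[gstart : gstart + flen]

            # genomic-orientation slices of the two mates
            left = (gstart, gstart + rl)
            right = (gstart + flen - rl, gstart + flen)
            if t.strand == "+":
                m1_slice, m2_slice = left, right
                m1_rev, m2_rev = False, True
            else:
                m1_slice, m2_slice = right, left
                m1_rev, m2_rev = True, False
            if config.orientation == "RF":
                m1_slice, m2_slice = m2_slice, m1_slice
                m1_rev, m2_rev = m2_rev, m1_rev

            k += 1
            name = f"seq.{k}"
            mates = []
            for mate_idx, (sl, rev) in enumerate(((m1_slice, m1_rev), (m2_slice, m2_rev))):
                genomic_seq = layout.seq[sl[0] : sl[1]]
                read_seq = revcomp(genomic_seq) if rev else genomic_seq
                read_seq = _apply_errors(read_seq, config.basewise_error, rng)
                genomic_seq = revcomp(read_seq) if rev else read_seq
                pos, cigar = layout.slice_alignment(sl[0], sl[1])
                mates.append((read_seq, genomic_seq, pos, cigar, rev))

            (r1, g1, p1, c1, rev1), (r2, g2, p2, c2, rev2) = mates
            fq1.write(f"@{name}/1\n{r1}\n+\n{'I' * rl}\n")
            fq2.write(f"@{name}/2\n{r2}\n+\n{'I' * rl}\n")

            for mate_idx, (rseq, gseq, pos, cigar, rev) in enumerate(mates):
                other = mates[1 - mate_idx]
                a = pysam.AlignedSegment(sam_header)
                a.query_name = name
                a.query_sequence = gseq
                a.query_qualities = qual
                a.reference_id = tid_of[layout.chrom]
                a.reference_start = pos
                a.cigartuples = cigar
                flag = 0x1 | 0x2
                flag |= 0x40 if mate_idx == 0 else 0x80
                if rev:
                    flag |= 0x10
                if other[4]:
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = tid_of[layout.chrom]
                a.next_reference_start = other[2]
                span_lo = min(p1, p2)
                ref_spans = [
                    p + sum(l for op, l in c if op in (0, 2, 3)) for p, c in ((p1, c1), (p2, c2))
                ]
                tlen = max(ref_spans) - span_lo
                a.template_length = tlen if pos == span_lo else -tlen
                sam_records.append(a)

            if is_intron_fragment:
                intronic_counts[t.id] += 1
                n_intronic += 1
            else:
                exonic_counts[t.id] += 1
            table_rows.append(
                (
                    name,
                    t.id,
                    t.gene_id,
                    layout.chrom,
                    t.strand,
                    int(is_intron_fragment),
                    p1,
                    _cigar_str(c1),
                    p2,
                    _cigar_str(c2),
                    flen,
                )
            )
    finally:
        fq1.close()
        fq2.close()

    sam_records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(str(sam_path), "wh", header=sam_header) as sam:
        for a in sam_records:
            sam.write(a)

    truth_table = pd.DataFrame(
        table_rows,
        columns=[
            "read_id",
            "transcript_id",
            "gene_id",
            "chrom",
            "strand",
            "intron_signal",
            "mate1_pos",
            "mate1_cigar",
            "mate2_pos",
            "mate2_cigar",
            "fragment_length",
        ],
    )
    counts = true_fpkm(exonic_counts, truth.annotation, config.read_length)
    counts["intronic_fragments"] = counts["transcript_id"].map(intronic_counts).fillna(0).astype(int)

    tt_path = outdir / "truth_table.tsv"
    quant_path = outdir / "truth_quant.tsv"
    truth_table.to_csv(tt_path, sep="\t", index=False)
    counts.to_csv(quant_path, sep="\t", index=False)
    if n_dropped:
        log.info("dropped %d fragments from molecules shorter than frag_min", n_dropped)

    return SimulationResult(
        truth_table=truth_table,
        true_counts=counts,
        n_dropped_short=n_dropped,
        n_intronic=n_intronic,
        variants=variant_list,
        paths={
            "fastq_1": fq1_path,
            "fastq_2": fq2_path,
            "sam": sam_path,
            "truth_table": tt_path,
            "truth_quant": quant_path,
        },
    )


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_str(cigar: List[Tuple[int, int]]) -> str:
    return "".join(f"{ln}{_CIGAR_OPS[op]}" for op, ln in cigar)


def true_fpkm(
    exonic_counts: Dict[str, int], annotation: Annotation, read_length: int
) -> pd.DataFrame:
    """Per-transcript true quantification from exonic fragment counts.

    FPKM_t = C_t / ((L_t / 1e3) * (N / 1e6)) with C_t the transcript's
    exonic fragment count, L_t its spliced length and N the total exonic
    fragment count; mean coverage is C_t * 2 * read_length / L_t (each
    fragment sequences two mates).  Intron-signal fragments are never
    counted as exonic.
    """
    n_total = sum(exonic_counts.values())
    if n_total == 0:
        raise SpliceBenchError("no exonic fragments: FPKM undefined")
    rows = []
    for tx_id, c in exonic_counts.items():
        length = annotation.transcript(tx_id).length
        fpkm = c / ((length / 1e3) * (n_total / 1e6))
        coverage = c * 2 * read_length / length
        rows.append((tx_id, c, length, fpkm, coverage))
    return pd.DataFrame(
        rows, columns=["transcript_id", "fragments", "length", "fpkm", "coverage"]
    )


def true_fpkm_from_table(
    truth_table: pd.DataFrame, annotation: Annotation, read_length: int
) -> pd.DataFrame:
    """True quantification recomputed from a truth table.

    Counts exonic fragments per transcript (intron-signal rows are
    excluded from the exonic count) and applies :func:`true_fpkm`.
    """
    exonic = truth_table[truth_table["intron_signal"] == 0]
    counts = exonic.groupby("transcript_id").size().to_dict()
    all_ids = truth_table["transcript_id"].unique()
    return true_fpkm({t: counts.get(t, 0) for t in all_ids}, annotation, read_length)
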