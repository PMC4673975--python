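"""Domain types for genomes, annotations and junction chains.

All coordinates are internally 0-based half-open; GTF/GFF I/O converts at
the boundary.  Strand is carried everywhere but junction coordinates are
always stored in genomic (ascending) order: matching of transcript models
is purely coordinate-based, so donor/acceptor naming is positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")


class SpliceBenchError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SpliceBenchError):
    """A file does not conform to its declared format."""


class ValidationError(SpliceBenchError):
    """An in-memory object violates a domain invariant."""


class CapacityError(SpliceBenchError):
    """A generator cannot satisfy a request within the given space."""


class NotApplicableError(SpliceBenchError):
    """An operation's precondition is not met by this input."""


@dataclass(frozen=True)
class Exon:
    """A contiguous span of genomic coordinates, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"exon start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionChain:
    """The ordered internal exon/exon boundary pairs of a transcript.

    This is the identity used to match predicted transcript models against
    truth: terminal (transcription start/end) coordinates are excluded.
    A transcript with n exons yields n-1 junctions; a single-exon
    transcript yields the empty chain.
    """

    chrom: str
    strand: str
    junctions: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = -1
        for donor, acceptor in self.junctions:
            if donor >= acceptor:
                raise ValidationError(f"junction donor {donor} >= acceptor {acceptor}")
            if donor <= prev:
                raise ValidationError("junctions not strictly increasing")
            prev = acceptor

    def __len__(self) -> int:
        return len(self.junctions)


@dataclass
class Transcript:
    """A stranded, chromosome-anchored ordered list of exons."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Exon, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        self.validate()

    def validate(self) -> None:
        if self.strand not in STRANDS and self.strand != ".":
            raise ValidationError(f"transcript {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                # introns must have positive length
                raise ValidationError(
                    f"transcript {self.id}: exons ({a.start},{a.end}) and "
                    f"({b.start},{b.end}) overlap or touch"
                )

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in bases."""
        return sum(e.length for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> int:
        """Unspliced genomic footprint, terminal to terminal."""
        return self.end - self.start

    def structure_key(self) -> tuple:
        """Full identity: junction chain plus terminal coordinates.

        Two splice forms may share their whole chain and still be distinct
        if the start or end of transcription differs.
        """
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))


def junction_chain(transcript: Transcript) -> JunctionChain:
    """Return the transcript's internal junction pairs in genomic order."""
    pairs = tuple(
        (a.end, b.start) for a, b in zip(transcript.exons, transcript.exons[1:])
    )
    return JunctionChain(transcript.chrom, transcript.strand, pairs)


@dataclass
class Gene:
    """A collection of transcripts sharing chromosome and strand."""

    id: str
    transcripts: List[Transcript] = field(default_factory=list)

    def validate(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(f"gene {self.id}: transcripts span chrom/strand")
        keys = [t.structure_key() for t in self.transcripts]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"gene {self.id}: duplicate transcript structures")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class Annotation:
    """A set of genes with a global transcript-id index."""

    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: Dict[str, Transcript] = {}
        self._gene_of: Dict[str, Gene] = {}
        for gene in self.genes:
            for t in gene.transcripts:
                if t.id in self._index:
                    raise ValidationError(f"duplicate transcript id {t.id}")
                self._index[t.id] = t
                self._gene_of[t.id] = gene

    def transcript(self, transcript_id: str) -> Transcript:
        return self._index[transcript_id]

    def gene_of(self, transcript_id: str) -> Gene:
        return self._gene_of[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes:
            yield from gene.transcripts

    @property
    def n_transcripts(self) -> int:
        return len(self._index)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        for gene in self.genes:
            gene.validate()


@dataclass
class Genome:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError("genome has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {name} is empty")

    def validate_alphabet(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name}: invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences
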