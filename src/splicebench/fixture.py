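"""Synthetic genomes and base annotations for self-contained benchmarking.

Stands in for a real genome build and its reference gene set: every other
module can be exercised with no download.  Sequences are i.i.d. bases at a
configurable GC fraction; genes are single-transcript, non-overlapping,
placed left to right with a guaranteed intergenic gap.  No splice-site
motifs are written — transcript inference is scored on coordinates, not
sequence, so motif realism buys nothing here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import yaml

from .core import Annotation, CapacityError, Exon, Gene, Genome, Transcript
from .rng import substream


@dataclass(frozen=True)
class DiscreteLaw:
    """A finite discrete distribution over positive integers."""

    values: tuple
    probs: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.values) != len(p) or len(p) == 0:
            raise ValueError("values and probs must be equal-length, non-empty")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def point(cls, value: int) -> "DiscreteLaw":
        return cls((int(value),), (1.0,))

    @classmethod
    def uniform_range(cls, lo: int, hi: int) -> "DiscreteLaw":
        """Uniform over the inclusive integer range [lo, hi]."""
        values = tuple(range(int(lo), int(hi) + 1))
        return cls(values, tuple(1.0 / len(values) for _ in values))

    @property
    def max(self) -> int:
        return max(self.values)

    @property
    def min(self) -> int:
        return min(self.values)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.choice(np.asarray(self.values), size=size, p=np.asarray(self.probs))

    def to_dict(self) -> dict:
        return {"values": list(self.values), "probs": list(map(float, self.probs))}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteLaw":
        return cls(tuple(d["values"]), tuple(d["probs"]))


@dataclass
class FixtureConfig:
    """Parameters of the synthetic genome and its base gene set."""

    n_chromosomes: int = 1
    chromosome_length: int = 1_000_000
    n_genes: int = 100
    exon_count_law: DiscreteLaw = field(default_factory=lambda: DiscreteLaw.uniform_range(5, 9))
    exon_length_law: DiscreteLaw = field(default_factory=lambda: DiscreteLaw.uniform_range(80, 300))
    intron_length_law: DiscreteLaw = field(default_factory=lambda: DiscreteLaw.uniform_range(100, 800))
    intergenic_gap_min: int = 200
    gc_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")
        for name in ("n_chromosomes", "chromosome_length", "n_genes", "intergenic_gap_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def max_gene_span(self) -> int:
        """Worst-case genomic footprint of one gene under the laws."""
        k = self.exon_count_law.max
        return k * self.exon_length_law.max + (k - 1) * self.intron_length_law.max

    def required_genome_length(self) -> int:
        """Capacity bound: total length that always fits ``n_genes``."""
        per_gene = self.max_gene_span() + 2 * self.intergenic_gap_min
        return self.n_genes * per_gene + self.n_chromosomes * 2 * self.intergenic_gap_min

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        for key in ("exon_count_law", "exon_length_law", "intron_length_law"):
            d[key] = d[key].to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FixtureConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("exon_count_law", "exon_length_law", "intron_length_law"):
            d[key] = DiscreteLaw.from_dict(d[key])
        return cls(**d)


def t1_scale_fixture_config(n_genes: int = 13300, seed: int = 0) -> FixtureConfig:
    """A fixture config sized (by the capacity bound) for a T1-style build.

    Defaults to 13,300 candidate genes, all with at least 5 exons, spread
    over 4 chromosomes — enough slack to absorb substituted genes when
    assembling a 13,000-gene truth set.
    """
    cfg = FixtureConfig(
        n_chromosomes=4,
        n_genes=n_genes,
        exon_count_law=DiscreteLaw.uniform_range(5, 9),
        exon_length_law=DiscreteLaw.uniform_range(80, 300),
        intron_length_law=DiscreteLaw.uniform_range(100, 800),
        seed=seed,
    )
    cfg.chromosome_length = -(-cfg.required_genome_length() // cfg.n_chromosomes)
    return cfg


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def generate_genome(config: FixtureConfig) -> Genome:
    """Draw i.i.d. bases with P(G)+P(C) = ``gc_fraction``; seeded."""
    rng = substream(config.seed, "fixture-genome")
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: Dict[str, str] = {}
    for i in range(config.n_chromosomes):
        draws = rng.choice(_BASES, size=config.chromosome_length, p=probs)
        sequences[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    return Genome(sequences)


def generate_annotation(genome: Genome, config: FixtureConfig) -> Annotation:
    """Place single-transcript genes greedily left to right.

    Gaps between consecutive genes are drawn uniformly in
    [gap_min, 2*gap_min], guaranteeing non-overlap; strands are uniform.
    Raises :class:`CapacityError` (stating the required length) when the
    genome cannot hold the requested gene count.
    """
    rng = substream(config.seed, "fixture-annotation")
    chroms = list(genome.sequences)
    genes: List[Gene] = []
    chrom_idx = 0
    cursor = config.intergenic_gap_min
    gap_lo, gap_hi = config.intergenic_gap_min, 2 * config.intergenic_gap_min
    for g in range(config.n_genes):
        n_exons = int(config.exon_count_law.sample(rng))
        exon_lens = config.exon_length_law.sample(rng, size=n_exons)
        intron_lens = config.intron_length_law.sample(rng, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        # advance to a chromosome with room for this gene
        while (
            chrom_idx < len(chroms)
            and cursor + span + config.intergenic_gap_min > len(genome[chroms[chrom_idx]])
        ):
            chrom_idx += 1
            cursor = config.intergenic_gap_min
        if chrom_idx >= len(chroms):
            raise CapacityError(
                f"genome too small for {config.n_genes} genes: need about "
                f"{config.required_genome_length()} bases total"
            )
        chrom = chroms[chrom_idx]
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append(Exon(pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g + 1:05d}"
        tx = Transcript(f"{gene_id}.1", gene_id, chrom, strand, tuple(exons))
        genes.append(Gene(gene_id, [tx]))
        cursor = pos + int(rng.integers(gap_lo, gap_hi + 1))
    return Annotation(genes)
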