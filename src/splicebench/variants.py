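"""Ground-truth annotations with controlled alternative-processing events.

Builds a systematic truth set in which every gene is labeled with exactly
one category of alternative transcript processing — exon skipping,
truncation (alternate transcription start/end realised by dropping
terminal exons), or splice-site shifts — and carries a controlled number
of splice forms, so downstream accuracy can be stratified by event type
and by forms per gene.  Event types are never mixed within one gene.

The default design: 1000 single-form genes with at least 5 exons, plus,
for each of the three categories, 1000 genes at each of 2, 3, 4 and 5
forms — 13,000 genes and 43,000 splice forms in total.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from .core import (
    Annotation,
    CapacityError,
    Exon,
    Gene,
    NotApplicableError,
    Transcript,
)
from .rng import substream

log = logging.getLogger(__name__)


class EventCategory(str, enum.Enum):
    SINGLE_FORM = "single_form"
    EXON_SKIPPING = "exon_skipping"
    TRUNCATION = "truncation"
    SPLICE_SHIFT = "splice_shift"


ALT_CATEGORIES = (
    EventCategory.EXON_SKIPPING,
    EventCategory.TRUNCATION,
    EventCategory.SPLICE_SHIFT,
)


@dataclass
class T1Design:
    """Layout of the systematic truth set.

    ``per_category_counts`` maps forms-per-gene (2..5) to the number of
    genes at that count, applied to each category in turn.
    """

    n_single_form_genes: int = 1000
    per_category_counts: Dict[int, int] = field(
        default_factory=lambda: {2: 1000, 3: 1000, 4: 1000, 5: 1000}
    )
    min_exons_single: int = 5
    min_gene_length: int = 200
    events_per_variant_mean: float = 0.5  # variant gets 1 + Poisson(mean) events
    shift_multiple3_prob: float = 0.9
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_single_form_genes + 3 * sum(self.per_category_counts.values())

    @property
    def n_transcripts(self) -> int:
        return self.n_single_form_genes + 3 * sum(
            f * n for f, n in self.per_category_counts.items()
        )

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["per_category_counts"] = {int(k): int(v) for k, v in d["per_category_counts"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "T1Design":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["per_category_counts"] = {int(k): int(v) for k, v in d["per_category_counts"].items()}
        return cls(**d)


@dataclass
class TruthAnnotation:
    """Truth annotation plus per-gene category and form-count labels."""

    annotation: Annotation
    gene_category: Dict[str, EventCategory]
    forms_per_gene: Dict[str, int]

    def category_of_transcript(self, tx_id: str) -> EventCategory:
        return self.gene_category[self.annotation.gene_of(tx_id).id]

    def forms_of_transcript(self, tx_id: str) -> int:
        return self.forms_per_gene[self.annotation.gene_of(tx_id).id]

    def write_tsv(self, path) -> None:
        """Sidecar table: transcript_id, gene_id, category, forms_in_gene."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["transcript_id", "gene_id", "category", "forms_in_gene"])
            for gene in self.annotation.genes:
                for t in gene.transcripts:
                    w.writerow(
                        [
                            t.id,
                            gene.id,
                            self.gene_category[gene.id].value,
                            self.forms_per_gene[gene.id],
                        ]
                    )

    @classmethod
    def read_tsv(cls, annotation: Annotation, path) -> "TruthAnnotation":
        gene_category: Dict[str, EventCategory] = {}
        forms: Dict[str, int] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                gene_category[row["gene_id"]] = EventCategory(row["category"])
                forms[row["gene_id"]] = int(row["forms_in_gene"])
        return cls(annotation, gene_category, forms)

    @classmethod
    def trivial(cls, annotation: Annotation) -> "TruthAnnotation":
        """Wrap an arbitrary annotation with unlabeled (single_form) genes."""
        cats = {g.id: EventCategory.SINGLE_FORM for g in annotation.genes}
        forms = {g.id: len(g.transcripts) for g in annotation.genes}
        return cls(annotation, cats, forms)


def select_base_transcripts(
    annotation: Annotation, min_exons: int, min_length: int
) -> List[Transcript]:
    """Filter base forms by exon count and spliced length, in input order.

    Mirrors the construction filters of the systematic truth set: very
    short genes are removed because the fragment-length law would leave
    them under-represented, and single-form genes must be multi-exon so
    junction-chain scoring is non-trivial.
    """
    return [
        t
        for t in annotation.transcripts()
        if len(t.exons) >= min_exons and t.length >= min_length
    ]


def exon_skipping_variant(base: Transcript, rng: np.random.Generator) -> Transcript:
    """Remove k internal exons, k ~ Uniform{1..min(2, n_internal)}.

    Terminal exons are always retained, so the event is purely a splicing
    change; the result always differs from the base by at least one
    junction.
    """
    n = len(base.exons)
    if n < 3:
        raise NotApplicableError(f"{base.id}: exon skipping needs >= 3 exons, has {n}")
    n_internal = n - 2
    k = int(rng.integers(1, min(2, n_internal) + 1))
    drop = set(rng.choice(np.arange(1, n - 1), size=k, replace=False).tolist())
    exons = tuple(e for i, e in enumerate(base.exons) if i not in drop)
    return Transcript(base.id, base.gene_id, base.chrom, base.strand, exons)


def truncation_variant(base: Transcript, rng: np.random.Generator) -> Transcript:
    """Drop a exons from the start and b from the end, a+b in [1, n-1].

    (a, b) is uniform over admissible pairs; at least one exon remains
    (possibly a single exon with an empty junction chain).  Models an
    alternate start/end of transcription.
    """
    n = len(base.exons)
    if n < 2:
        raise NotApplicableError(f"{base.id}: truncation needs >= 2 exons")
    pairs = [(a, b) for a in range(n) for b in range(n - a) if 1 <= a + b <= n - 1]
    a, b = pairs[int(rng.integers(len(pairs)))]
    exons = base.exons[a : n - b]
    return Transcript(base.id, base.gene_id, base.chrom, base.strand, exons)


_SHIFT_MULT3 = np.array([-9, -6, -3, 3, 6, 9])
_SHIFT_OTHER = np.array([-2, -1, 1, 2])


def splice_shift_variant(
    base: Transcript,
    rng: np.random.Generator,
    multiple3_prob: float = 0.9,
    max_tries: int = 100,
) -> Transcript:
    """Shift one junction-adjacent exon boundary by a small offset.

    With probability ``multiple3_prob`` the offset is +/-3, 6 or 9 (frame
    preserving, as typically observed in real alternative splice sites),
    otherwise +/-1 or 2.  A draw that would collapse an exon or an intron
    is rejected and redrawn.  Exactly one junction coordinate changes.
    """
    n = len(base.exons)
    if n < 2:
        raise NotApplicableError(f"{base.id}: splice shift needs >= 2 exons")
    # junction-adjacent boundaries: end of exon i (i < n-1), start of exon i (i > 0)
    boundaries = [("end", i) for i in range(n - 1)] + [("start", i) for i in range(1, n)]
    for _ in range(max_tries):
        side, i = boundaries[int(rng.integers(len(boundaries)))]
        if rng.random() < multiple3_prob:
            delta = int(_SHIFT_MULT3[rng.integers(len(_SHIFT_MULT3))])
        else:
            delta = int(_SHIFT_OTHER[rng.integers(len(_SHIFT_OTHER))])
        e = base.exons[i]
        if side == "end":
            new_exon = (e.start, e.end + delta)
            intron_ok = new_exon[1] < base.exons[i + 1].start
        else:
            new_exon = (e.start + delta, e.end)
            intron_ok = base.exons[i - 1].end < new_exon[0]
        if new_exon[0] < new_exon[1] and intron_ok and new_exon[0] >= 0:
            exons = list(base.exons)
            exons[i] = Exon(*new_exon)
            return Transcript(base.id, base.gene_id, base.chrom, base.strand, tuple(exons))
    raise NotApplicableError(f"{base.id}: no admissible splice shift found")


_VARIANT_OPS = {
    EventCategory.EXON_SKIPPING: lambda t, rng, d: exon_skipping_variant(t, rng),
    EventCategory.TRUNCATION: lambda t, rng, d: truncation_variant(t, rng),
    EventCategory.SPLICE_SHIFT: lambda t, rng, d: splice_shift_variant(
        t, rng, d.shift_multiple3_prob
    ),
}


def make_variant(
    base: Transcript,
    category: EventCategory,
    rng: np.random.Generator,
    design: Optional[T1Design] = None,
) -> Transcript:
    """Apply 1 + Poisson(mean) events of one category to a base form.

    One transcript can carry several modifications, always of the same
    type; the event count is capped by admissibility (an event that can
    no longer apply, e.g. skipping in a 2-exon intermediate, ends the
    chain early).
    """
    design = design or T1Design()
    op = _VARIANT_OPS[category]
    n_events = 1 + int(rng.poisson(design.events_per_variant_mean))
    out = base
    for _ in range(n_events):
        try:
            out = op(out, rng, design)
        except NotApplicableError:
            if out is base:
                raise
            break
    return out


def build_t1_truth(annotation: Annotation, design: T1Design) -> TruthAnnotation:
    """Assemble the systematic truth set from a single-form annotation.

    Genes are assigned to slots in input order: single-form genes first,
    then, for each category, blocks of genes at 2..5 forms.  Additional
    forms are generated by that category's operation until the requested
    number of pairwise-distinct forms exists; a gene for which distinct
    forms cannot be produced within a bounded number of retries is
    replaced by the next candidate (logged).  Deterministic given
    ``design.seed``.
    """
    rng = substream(design.seed, "t1-variants")
    candidates = select_base_transcripts(
        annotation, design.min_exons_single, design.min_gene_length
    )
    slots: List[tuple] = [(EventCategory.SINGLE_FORM, 1)] * design.n_single_form_genes
    for category in ALT_CATEGORIES:
        for f in sorted(design.per_category_counts):
            slots.extend([(category, f)] * design.per_category_counts[f])

    genes: List[Gene] = []
    gene_category: Dict[str, EventCategory] = {}
    forms_per_gene: Dict[str, int] = {}
    it = iter(candidates)

    for category, f in slots:
        while True:
            base = next(it, None)
            if base is None:
                raise CapacityError(
                    f"ran out of candidate genes after {len(genes)} of "
                    f"{len(slots)}; supply a larger base annotation"
                )
            forms = _make_gene_forms(base, category, f, rng, design)
            if forms is None:
                log.warning(
                    "gene %s: could not produce %d distinct %s forms; substituting",
                    base.gene_id,
                    f,
                    category.value,
                )
                continue
            gene = Gene(base.gene_id, forms)
            genes.append(gene)
            gene_category[gene.id] = category
            forms_per_gene[gene.id] = f
            break

    return TruthAnnotation(Annotation(genes), gene_category, forms_per_gene)


def _make_gene_forms(
    base: Transcript,
    category: EventCategory,
    n_forms: int,
    rng: np.random.Generator,
    design: T1Design,
    max_tries_per_form: int = 40,
) -> Optional[List[Transcript]]:
    """Produce n pairwise-distinct forms of one gene, or None on failure."""
    forms = [base]
    seen = {base.structure_key()}
    while len(forms) < n_forms:
        for _ in range(max_tries_per_form):
            try:
                var = make_variant(base, category, rng, design)
            except NotApplicableError:
                return None
            key = var.structure_key()
            if key not in seen:
                seen.add(key)
                var.id = f"{base.id}.v{len(forms)}"
                forms.append(var)
                break
        else:
            return None
    return forms
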