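"""Deliberately imperfect "provided" annotations for guided assembly.

Real annotation is never perfect: it misses transcripts that are
expressed and contains models that are not.  The corruptor emulates both
defects — it hides a fraction of the expressed transcripts, and can
replace each hidden one with a newly generated unexpressed splice form of
the same gene (a decoy).  A full ledger of what was hidden, planted and
retained is emitted so the evaluator can stratify accuracy by annotation
status.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Set

from .core import Annotation, Gene, NotApplicableError, Transcript
from .evaluate import single_exon_match
from .rng import substream
from .simulate import ExpressionProfile
from .variants import EventCategory, T1Design, TruthAnnotation, make_variant

log = logging.getLogger(__name__)


@dataclass
class CorruptionLedger:
    hidden_expressed: Set[str] = field(default_factory=set)
    planted_decoys: Set[str] = field(default_factory=set)
    retained: Set[str] = field(default_factory=set)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["transcript_id", "status"])
            rows = (
                [(t, "retained") for t in sorted(self.retained)]
                + [(t, "hidden_expressed") for t in sorted(self.hidden_expressed)]
                + [(t, "planted_decoy") for t in sorted(self.planted_decoys)]
            )
            w.writerows(rows)

    @classmethod
    def read_tsv(cls, path) -> "CorruptionLedger":
        ledger = cls()
        buckets = {
            "retained": ledger.retained,
            "hidden_expressed": ledger.hidden_expressed,
            "planted_decoy": ledger.planted_decoys,
        }
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                buckets[row["status"]].add(row["transcript_id"])
        return ledger


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _decoy_is_distinct(decoy: Transcript, gene_forms: List[Transcript]) -> bool:
    """A decoy must not score as a true positive against any real form."""
    d_chain = tuple((a.end, b.start) for a, b in zip(decoy.exons, decoy.exons[1:]))
    for form in gene_forms:
        if decoy.structure_key() == form.structure_key():
            return False
        f_chain = tuple((a.end, b.start) for a, b in zip(form.exons, form.exons[1:]))
        if d_chain and d_chain == f_chain:
            return False
        if not d_chain and len(form.exons) == 1 and single_exon_match(
            decoy.exons[0], form.exons[0]
        ):
            return False
    return True


def corrupt_annotation(
    truth: TruthAnnotation,
    profile: ExpressionProfile,
    hide_fraction: float,
    replace: bool,
    seed: int,
) -> tuple:
    """Hide expressed transcripts; optionally plant decoys in their place.

    Selects round(hide_fraction * n_expressed) expressed transcripts
    uniformly at random and removes them from the provided annotation.
    With ``replace`` set, each hidden transcript is replaced by a freshly
    generated unexpressed variant of the same gene (using the gene's
    event category where known, exon skipping otherwise), structurally
    distinct from every real form; genes where no decoy is constructible
    are hidden without replacement (logged).  Without ``replace`` the
    annotation simply shrinks — appropriate when the expression spectrum
    already leaves many annotated models unexpressed.

    Returns (provided :class:`Annotation`, :class:`CorruptionLedger`).
    """
    if not (0.0 <= hide_fraction <= 1.0):
        raise ValueError("hide_fraction must lie in [0, 1]")
    rng = substream(seed, "corruption")
    expressed = sorted(t for t, w in profile.items() if w > 0 and t in truth.annotation)
    n_hide = _round_half_up(hide_fraction * len(expressed))
    hidden = set(
        rng.choice(expressed, size=n_hide, replace=False).tolist() if n_hide else []
    )

    design = T1Design(seed=seed)
    ledger = CorruptionLedger(hidden_expressed=set(hidden))
    genes: List[Gene] = []
    for gene in truth.annotation.genes:
        kept = [t for t in gene.transcripts if t.id not in hidden]
        ledger.retained.update(t.id for t in kept)
        n_hidden_here = len(gene.transcripts) - len(kept)
        if replace and n_hidden_here:
            category = truth.gene_category.get(gene.id, EventCategory.SINGLE_FORM)
            if category == EventCategory.SINGLE_FORM:
                category = EventCategory.EXON_SKIPPING
            existing = list(gene.transcripts) + kept
            for j in range(n_hidden_here):
                decoy = _make_decoy(gene, category, rng, design, existing)
                if decoy is None:
                    log.warning(
                        "gene %s: no constructible decoy; hiding without replacement",
                        gene.id,
                    )
                    continue
                decoy.id = f"{gene.id}.decoy{j + 1}"
                kept.append(decoy)
                existing.append(decoy)
                ledger.planted_decoys.add(decoy.id)
        if kept:
            genes.append(Gene(gene.id, kept))
    return Annotation(genes), ledger


def _make_decoy(
    gene: Gene,
    category: EventCategory,
    rng,
    design: T1Design,
    existing: List[Transcript],
    max_tries: int = 40,
):
    base = max(gene.transcripts, key=lambda t: len(t.exons))
    fallback_order = [category] + [
        c
        for c in (
            EventCategory.EXON_SKIPPING,
            EventCategory.SPLICE_SHIFT,
            EventCategory.TRUNCATION,
        )
        if c != category
    ]
    for cat in fallback_order:
        for _ in range(max_tries):
            try:
                decoy = make_variant(base, cat, rng, design)
            except NotApplicableError:
                break
            if _decoy_is_distinct(decoy, existing):
                return decoy
    return None
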