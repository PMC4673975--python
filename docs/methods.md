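# Methods

This note records the models behind each stage of the toolkit, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic genomes and base gene sets

Chromosome sequences are i.i.d. bases with P(G)+P(C) equal to the
configured GC fraction (default 0.42, a typical mammalian bulk value).
Genes are single-transcript and placed left to right; the gap between
consecutive genes is drawn uniformly in [gap_min, 2·gap_min]
(default gap_min 200 bases), which guarantees non-overlap by
construction — the evaluation design assumes non-overlapping genes so
that false positives can be attributed to one locus. Exon counts, exon
lengths and intron lengths come from user-configurable discrete laws
(defaults: counts uniform on 5–9, exon lengths uniform on 80–300,
introns uniform on 100–800 bases, chosen to resemble compact mammalian
protein-coding genes while keeping fixtures small). A capacity bound
(`FixtureConfig.required_genome_length`) sizes the genome from the law
maxima, so a requested gene count either fits or fails fast with the
required length.

No splice-site motifs are written into the sequence. Transcript
inference is scored purely on coordinates, and no method being
benchmarked uses the genome sequence beyond alignment, so motif realism
would add nothing the metrics can see.

What the fixture does **not** emulate: isochore/repeat structure,
overlapping or nested genes, pseudogenes, and realistic splice signals.
Passing tests on fixtures therefore say nothing about alignment
difficulty on repetitive sequence; they validate the bookkeeping and the
metric definitions exactly, which is what they are for.

## Systematic truth sets

A truth set assigns every gene exactly one event category and a target
number of splice forms. The default design is 1,000 single-form genes
(each with at least 5 exons) plus, for each of the three categories,
1,000 genes at each of 2, 3, 4 and 5 forms: 13,000 genes, 43,000 forms.
Categories are never mixed within a gene, so per-category accuracy is
cleanly separable. Candidate genes shorter than 200 bases are excluded,
because the fragment-length law would leave them under-represented.

Per-variant event count is 1 + Poisson(0.5), capped by admissibility: a
variant usually carries one event, occasionally several of the same
type. The individual events:

* **exon skipping** removes k internal exons, k uniform on
  {1, …, min(2, n_internal)}; terminal exons are kept so the change is
  purely internal.
* **truncation** removes a prefix of a exons and/or a suffix of b exons,
  (a, b) uniform over pairs with 1 ≤ a+b ≤ n−1. A single remaining exon
  (empty junction chain) is allowed: an alternate transcription
  start/end can legitimately reduce a form to one exon.
* **splice shift** moves one junction-adjacent exon boundary by δ, with
  δ ∈ {±3, ±6, ±9} with probability 0.9 (frame-preserving shifts
  dominate real alternative splice sites) and δ ∈ {±1, ±2} otherwise;
  draws that would collapse an exon or an intron are rejected and
  redrawn. Both the 0.9 mixture weight and the event-count mean are
  config-exposed, since only the qualitative behaviour ("mostly
  multiples of three", "can have several modifications") is fixed by the
  design.

Distinctness of forms is tested on junction chain *plus* terminal
coordinates, because two forms may share every junction and differ only
in where transcription starts or ends. A gene that cannot produce the
requested number of distinct forms within a bounded number of retries is
substituted by the next candidate (logged), which is why fixture configs
carry ~2% spare genes.

## Read simulation

Fragments are drawn with replacement from a multinomial over transcripts
with probability proportional to molecule weight. Two expression models:

* **uniform coverage** (weight ∝ spliced length): every transcript gets
  the same expected per-base depth; the fragment count is solved from
  the target depth as ceil(target · ΣL / (2 · read_length)), since each
  fragment sequences two mates.
* **exponential**: each transcript is independently expressed with
  probability 2/3 and expressed transcripts get weight from
  Exponential(rate = 0.01); this produces the long-tailed spectrum seen
  in real libraries. Both the rate parameterisation and the expressed
  fraction are config-exposed.

Fragment length is Normal(median 300, sd 1000/3) rounded to an integer
and rejected outside [200, 500] (defaults; all five numbers
configurable). A fragment whose source molecule is shorter than the
drawn length has its length redrawn; molecules shorter than frag_min
contribute no fragments at all — short genes are under-represented by
design, exactly as fragmentation under-represents them in a real
library. Dropped draws are counted and logged.

The protocol is strand-specific, forward-stranded by default (mate 1 on
the transcript strand, mate 2 its reverse complement from the other
fragment end; RF is a flag). Qualities are constant Phred 40, because
error is modelled by rate, not by a quality profile.

Noise processes, all off by default and raised together by
`SimulationConfig.realistic()` (basewise error 0.5%, substitutions 0.1%,
indels 0.05%, intron frequency 30%):

* **polymorphisms** are applied to the genome once, before simulation:
  per-base substitution to a uniformly chosen different base, and
  per-base indel seeding with insertion/deletion at equal odds and
  length uniform on {1, 2, 3} (small indels dominate real polymorphism;
  the law is config-exposed). Reads are extracted from the polymorphic
  haplotype — one haplotype, as a homozygous sample — while the truth
  SAM is expressed against the *reference* through a monotone
  piecewise coordinate map, so aligner output is directly comparable.
  CIGARs carry I/D at indels and N across spliced-over introns; N
  lengths are reference intron lengths by construction.
* **intron signal**: with the configured per-fragment probability the
  fragment is drawn from the unspliced pre-mRNA span of its source
  transcript instead of the mature molecule. Because introns are much
  longer than exons, the same fragment mass spreads over far more bases
  and intronic depth stays well below exonic depth — the property that
  makes intron signal a realistic confounder rather than a second
  expression signal. Intron-signal fragments are flagged in the truth
  table and never counted as exonic.

True FPKM is computed from the *realised* exonic fragment counts, not
from the theoretical intensities: FPKM_t = C_t / ((L_t/10³)(N/10⁶)).
Counts are of fragments (read pairs), not single reads; mean coverage is
C_t · 2 · read_length / L_t.

## Annotation corruption

round_half_up(hide_fraction · n_expressed) expressed transcripts are
hidden uniformly at random. With replacement on, each hidden form is
replaced by a freshly generated unexpressed variant of the same gene,
generated with the gene's own event category (exon skipping as the
fallback) and required to be structurally distinct from every real form
under the *evaluator's* matching rule — including the single-exon
reciprocal-overlap rule — so a decoy can never score as a true positive.
Genes where no decoy is constructible are hidden without replacement and
logged. `hide_fraction` is deliberately a required argument with no
default. Replacement is a flag: with a realistic expression spectrum a
third of the annotation is already unexpressed and planting more decoys
is unnecessary.

## Evaluation

Matching is strand-aware; unstranded predictions ('.') match either
strand (logged). Multiple predictions matching one truth form count as
one TP with the surplus deduplicated — neither TP nor FP — so redundant
output neither inflates recall nor deflates precision. False negatives
are assessed only against transcripts with at least
`fn_expression_threshold` true exonic fragments (default 1): a form that
received no fragments cannot reasonably be demanded.

Strata: annotation status (provided vs hidden, from the corruption
ledger), event category, forms per gene, and depth-of-coverage bins
[1, 10), [10, 100), [100, ∞); coverage below 1 is unbinned. Counts,
precision, recall and the comfort-zone flag (recall ≥ 0.25 and
precision ≥ 2/3) are reported per stratum; empty denominators are marked
undefined rather than coerced to 0 or 1.

A false positive has no truth transcript, so stratified precision needs
an attribution rule: each FP is assigned to the truth gene whose genomic
span it overlaps most on its chromosome (strand-compatible), inheriting
that gene's category and form count, the coverage bin of the gene's
best-covered form, and status "hidden" when the gene contains hidden
transcripts. Unattributable FPs count only toward overall precision.
This is an attribution convention, not part of the metric definitions;
overall counts never depend on it. Relatedly, per-stratum TP counts
detected *expressed* forms; a prediction matching an unexpressed truth
form is a TP at the prediction level (it is not penalised) but is not
credited in stratum counts, keeping precision and recall over the same
population of expressed forms.

Quantification agreement removes on/off errors (true 0 inferred > 0, or
true > 0 inferred 0), then extreme outliers (|log10(inferred/true)| > 2,
removed count always reported so the filter's effect is visible — the
bound is a convention and config-exposed), and computes Pearson r on the
survivors; fewer than 3 survivors leaves r undefined.

Base-level alignment accuracy: a sequenced base is accurate iff the test
alignment places it at the same reference coordinate as the truth
alignment; the denominator is truth-aligned bases (bases the truth
itself leaves unaligned, i.e. inserted bases, are excluded), and
unaligned or missing test reads contribute only inaccuracy.

## Numerical and reproducibility choices

One run seed is expanded into named, statistically independent
substreams (SeedSequence spawning keyed by a CRC of the stream name), so
e.g. changing the fragment count cannot perturb variant design. All
writers emit deterministic bytes for fixed inputs; SAM output is
coordinate-sorted with @SQ headers from the reference. Internal
coordinates are 0-based half-open with a single conversion site at the
GTF boundary (GTF is 1-based inclusive). GFF3 is accepted on input
through the ID/Parent mapping; output is GTF only.

## Problem sizes used in the checks

The full 13,000-gene truth-set composition is verified at scale (it
builds in well under a minute). Distributional checks use 10⁵
fragment-length draws, 30,000 transcripts for the expressed fraction,
and a 100-gene fixture at 40× for coverage — sizes at which the binomial
or chi-square tolerances quoted alongside each check are decisive.
End-to-end closure runs on a 40-gene multi-form world with exons of at
least 200 bases so that every variant molecule can hold fragments,
making the hidden/decoy counting identities exact rather than
approximate.

## Known limitations

No positional or library-preparation bias is simulated (real ribosomal
depletion and polyA protocols deviate strongly from uniform coverage);
no quality-score profiles; no PCR duplicates; one polymorphic haplotype;
no overlapping genes. Scores are transcript-level only — exon- or
junction-level accuracy, statistical comparison across tools, and
plotting are intentionally out of scope (reports are TSV).
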