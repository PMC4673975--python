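"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from splicebench import (
    Annotation,
    DiscreteLaw,
    Exon,
    FixtureConfig,
    Gene,
    Transcript,
    TruthAnnotation,
    generate_annotation,
    generate_genome,
)


def make_transcript(exons, tx_id="t1", gene_id="g1", chrom="chr1", strand="+"):
    return Transcript(tx_id, gene_id, chrom, strand, tuple(Exon(a, b) for a, b in exons))


@pytest.fixture
def five_exon_transcript():
    return make_transcript(
        [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    )


@pytest.fixture
def toy_fixture_config():
    return FixtureConfig(
        n_genes=20,
        chromosome_length=300_000,
        exon_count_law=DiscreteLaw.uniform_range(5, 8),
        exon_length_law=DiscreteLaw.uniform_range(100, 250),
        intron_length_law=DiscreteLaw.uniform_range(100, 500),
        seed=17,
    )


@pytest.fixture
def toy_genome(toy_fixture_config):
    return generate_genome(toy_fixture_config)


@pytest.fixture
def toy_annotation(toy_fixture_config, toy_genome):
    return generate_annotation(toy_genome, toy_fixture_config)


@pytest.fixture
def toy_truth(toy_annotation):
    return TruthAnnotation.trivial(toy_annotation)


class ScriptedRng:
    """A stand-in generator that replays scripted draws, for hand-traced
    variant examples."""

    def __init__(self, integers=(), randoms=(), poissons=()):
        self._integers = list(integers)
        self._randoms = list(randoms)
        self._poissons = list(poissons)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def random(self, *args, **kwargs):
        return self._randoms.pop(0)

    def poisson(self, *args, **kwargs):
        return self._poissons.pop(0)

    def choice(self, values, size=None, replace=True, p=None):
        idx = self._integers.pop(0)
        values = np.asarray(values)
        if size is None:
            return values[idx]
        return values[np.asarray(idx)]


@pytest.fixture
def scripted_rng():
    return ScriptedRng
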