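"""Seed handling: one global seed expanded into named substreams.

Every module draws from its own independent stream derived from the run
seed and a stream name, so e.g. adding fragments to a simulation does not
perturb variant design in the same run.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for (seed, name).

    Streams for distinct names are statistically independent; the same
    (seed, name) pair always yields the same stream.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
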