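from __future__ import annotations

import random

import numpy as np
import pytest

from editscan import GuideTarget


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def guide(rng):
    """A 19-nt NGG guide, the construct length used throughout."""
    return GuideTarget("g1", random_dna(rng, 19))


@pytest.fixture
def nprng():
    return np.random.default_rng(1234)


def hits_as_tuples(hits):
    """Project MatchHits onto the fields the brute-force oracle reports."""
    return sorted((h.strand, h.start, h.end, h.mismatches, h.bulge) for h in hits)
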