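import random

import numpy as np
import pytest

from crevip.io import GenomicRegion, MotifPFM


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def pyrng():
    return random.Random(0)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def sharp_pfm():
    """A sharp 8-long PFM with consensus GATTACAG."""
    consensus = "GATTACAG"
    matrix = np.full((4, len(consensus)), 2.0)
    for j, base in enumerate(consensus):
        matrix["ACGT".index(base), j] = 94.0
    return MotifPFM(id="M_TEST", name="TESTTF", matrix=matrix)


@pytest.fixture
def toy_genome(rng):
    """A 100 kb single-contig genome string."""
    return {"chr1": random_seq(rng, 100_000)}
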