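import numpy as np
import pytest
from hypothesis import settings

import kmerbin as kb

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_db(rng):
    """A 5-sequence k=15 database plus its source sequences."""
    seqs = [random_seq(rng, 300) for _ in range(5)]
    return kb.build_database(seqs, 15, "g0"), seqs


@pytest.fixture(scope="session")
def tiny_fixture():
    """A small labelled community: 2 phyla x 2 genera, 20 kb genomes."""
    params = kb.FixtureParams(
        genome_length=20_000, n_reads=400, read_length=150, substitution_rate=0.01
    )
    return kb.simulate_fixture(params, seed=7)


def brute_force_kmers(seqs, k):
    """Independent oracle: every ACGT-only window, via a plain hash set."""
    out = set()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                out.add(w)
    return out


def interval_union_score(read, ref_kmers, k):
    """Independent oracle for the match score: mark every base covered
    by a window present in the k-mer set, count the marks."""
    read = read.upper()
    covered = [False] * len(read)
    for i in range(len(read) - k + 1):
        w = read[i : i + k]
        if set(w) <= set("ACGT") and w in ref_kmers:
            for j in range(i, i + k):
                covered[j] = True
    return sum(covered)
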