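"""Shared fixtures: small deterministic read sets and random-instance makers."""

from __future__ import annotations

import numpy as np
import pytest

from readnorm import Read, ReadPair, build_fixture


@pytest.fixture
def tiny():
    """The 4-read worked example (k=3, b=2, forward-strand labels)."""
    reads, params = build_fixture("tiny")
    return reads, params


@pytest.fixture(scope="session")
def skew_fixture():
    """Seed-pinned dataset with systematically low-quality reads early."""
    return build_fixture("ordering-skew")


@pytest.fixture(scope="session")
def paired_fixture():
    return build_fixture("paired-small")


def random_reads(
    rng: np.random.Generator,
    n: int,
    genome_len: int = 120,
    min_len: int = 8,
    max_len: int = 25,
    n_rate: float = 0.02,
) -> list[Read]:
    """Reads sampled from a tiny random genome, so labels are shared;
    occasional N characters and full-range random qualities."""
    bases = "ACGT"
    genome = "".join(rng.choice(list(bases), size=genome_len))
    reads = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome_len - length + 1))
        seq = list(genome[start : start + length])
        for j in range(length):
            if rng.random() < n_rate:
                seq[j] = "N"
        qual = "".join(chr(33 + int(q)) for q in rng.integers(0, 42, size=length))
        reads.append(Read(id=f"r{i}", seq="".join(seq), qual=qual))
    return reads


def random_pairs(rng: np.random.Generator, n: int, **kw) -> list[ReadPair]:
    lefts = random_reads(rng, n, **kw)
    rights = random_reads(rng, n, **kw)
    return [
        ReadPair(left=l, right=r, index=i)
        for i, (l, r) in enumerate(zip(lefts, rights))
    ]
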