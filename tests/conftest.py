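"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the FM-index code path: occurrence
counts and positions are computed by enumerating windows of each read in
the plain text, and the reference suffix order by sorting rotations with
Python's ``sorted``.
"""

from collections import Counter, defaultdict

import numpy as np
import pytest

from readprobe import store_from_sequences
from readprobe.simulate import make_genome


def naive_rotation_order(text: str) -> list[int]:
    """Reference suffix order: sort rotations, final sentinel smallest.

    Mirrors the index's convention from first principles: the terminator
    sorts below the read separators, which sort below the bases.
    """
    trans = str.maketrans({"$": "\x01"})
    t = text[:-1].translate(trans) + "\x00"
    doubled = t + t
    n = len(t)
    return sorted(range(n), key=lambda i: (doubled[i : i + n], i))


def kmer_positions(store, k: int) -> dict[str, list[int]]:
    """Every k-window of every read segment, keyed by k-mer -> text positions."""
    out: dict[str, list[int]] = defaultdict(list)
    offsets = store.offsets
    for seg in range(store.n_segments):
        start = int(offsets[seg])
        seq = store.text[start : start + int(store.seg_lengths[seg])]
        for j in range(len(seq) - k + 1):
            out[seq[j : j + k]].append(start + j)
    return out


def naive_count(store, pattern: str) -> int:
    """Occurrences of pattern inside reads (never across sentinels)."""
    total = 0
    offsets = store.offsets
    for seg in range(store.n_segments):
        start = int(offsets[seg])
        seq = store.text[start : start + int(store.seg_lengths[seg])]
        i = seq.find(pattern)
        while i != -1:
            total += 1
            i = seq.find(pattern, i + 1)
    return total


def random_reads(rng: np.random.Generator, n_reads: int, read_len: int) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bases[rng.integers(0, 4, size=read_len)].tobytes().decode("ascii")
        for _ in range(n_reads)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_store(rng):
    return store_from_sequences(random_reads(rng, 30, 80))


@pytest.fixture
def toy_genome():
    return make_genome(2000, seed=7)
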