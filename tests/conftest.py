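"""Shared fixtures: library designs and small synthetic pools."""

import pytest

from selexkit.pool import LibraryDesign, ReadSet, count_pool
from selexkit.synth import STANDIN_DESIGN

SCA21_MOTIF = "AGTGGGGTTCGGGTGGAGTT"


@pytest.fixture
def design() -> LibraryDesign:
    return STANDIN_DESIGN


@pytest.fixture
def motif() -> str:
    return SCA21_MOTIF


def dna_id(i: int, length: int = 30) -> str:
    """Unique DNA string for integer i: base-4 encoding over ACGT."""
    digits = []
    while i:
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(digits)).rjust(length, "A")


def make_counts(seq_copies: dict[str, int], pool_id: str = "test") -> "PoolCounts":
    """PoolCounts from explicit sequence -> copy-number mapping."""
    records = []
    i = 0
    for seq, n in seq_copies.items():
        for _ in range(n):
            records.append((f"r{i}", seq, None))
            i += 1
    return count_pool(ReadSet(pool_id=pool_id, records=records))


@pytest.fixture
def tiny_pool():
    """Three unique 30-mers at 3:1:1 copies."""
    a, c, g = "A" * 30, "C" * 30, "G" * 30
    return make_counts({a: 3, c: 1, g: 1})
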