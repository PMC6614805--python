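"""Selection-pool enrichment analysis.

Turns raw sequencing reads of SELEX rounds into per-sequence abundances,
motif-family trajectories across rounds, and pool-diversity summaries.

A library strand is a stem-loop: forward primer region + 5' stem
(together the *forward flank*), a fixed-length random region (the loop,
the putative binding domain), then the 3' stem + reverse primer region
(the *reverse flank*).  Analysis operates on the random region only:
reads are trimmed to it, exact duplicates are collapsed, and a
*family* is the set of unique sequences whose random region contains a
defining motif as an exact substring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReadSet",
    "LibraryDesign",
    "PoolCounts",
    "PoolEntry",
    "TrimReport",
    "FamilyTrajectory",
    "PoolSummary",
    "trim_to_random_region",
    "count_pool",
    "family_fraction",
    "combine_pools",
    "pool_summary",
    "enrichment_trajectory",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass
class ReadSet:
    """Reads of one selection pool.

    records are (read_id, sequence, quality) triples; quality may be None
    (it is never used downstream).
    """

    pool_id: str
    records: list[tuple[str, str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pool_id:
            raise ValueError("pool_id must be non-empty")
        for rid, seq, _q in self.records:
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"read {rid!r} contains invalid characters {sorted(bad)}; "
                    "sequences must be uppercase A/C/G/T/N"
                )

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.records]


@dataclass(frozen=True)
class LibraryDesign:
    """Geometry of the stem-loop library strand.

    forward_flank = forward primer region + 5' stem; reverse_flank =
    3' stem + reverse primer region.  Lengths must add up to the full
    strand length.
    """

    forward_flank: str
    reverse_flank: str
    random_length: int = 30
    total_length: int = 73

    def __post_init__(self) -> None:
        if not self.forward_flank or not self.reverse_flank:
            raise ValueError("flank sequences must be non-empty")
        if len(self.forward_flank) + self.random_length + len(self.reverse_flank) \
                != self.total_length:
            raise ValueError(
                "inconsistent design: len(forward_flank) + random_length + "
                "len(reverse_flank) must equal total_length"
            )


@dataclass(frozen=True)
class PoolEntry:
    """One unique random-region sequence in a counted pool."""

    sequence: str
    reads: int
    fraction: float
    rpm: float


@dataclass
class TrimReport:
    kept: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.discarded


@dataclass
class PoolCounts:
    """Unique-sequence abundances of one trimmed pool.

    total_reads is the read count before trimming (R_t); fractions are
    over successfully trimmed reads.
    """

    pool_id: str
    total_reads: int
    entries: dict[str, PoolEntry]

    @property
    def trimmed_reads(self) -> int:
        return sum(e.reads for e in self.entries.values())

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def ranked(self) -> list[PoolEntry]:
        """Entries sorted by reads descending, ties broken lexicographically."""
        return sorted(self.entries.values(), key=lambda e: (-e.reads, e.sequence))

    def fractions(self) -> np.ndarray:
        return np.array([e.fraction for e in self.entries.values()])


@dataclass
class FamilyTrajectory:
    """Motif-family abundance across ordered selection rounds."""

    motif: str
    per_round: dict[str, float]
    medians: dict[str, float]


@dataclass
class PoolSummary:
    """Diversity summary of one pool's per-unique-sequence fractions."""

    percentiles: dict[int, float]
    max_fraction: float
    n_unique: int


def _find_with_mismatches(read: str, pattern: str, start: int, max_mm: int) -> int:
    """Leftmost index >= start where pattern matches read with <= max_mm
    Hamming mismatches; -1 if none."""
    if max_mm == 0:
        return read.find(pattern, start)
    m = len(pattern)
    for i in range(start, len(read) - m + 1):
        mm = 0
        for a, b in zip(read[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return i
    return -1


def trim_to_random_region(
    reads: ReadSet,
    design: LibraryDesign,
    max_mismatches: int = 0,
) -> tuple[ReadSet, TrimReport]:
    """Extract the random region from each read by locating both flanks.

    A read is kept only if the forward flank is found, the reverse flank is
    found downstream of it, and the region between them has exactly
    ``design.random_length`` bases.  Everything else is discarded and
    counted.  Matching is exact by default; ``max_mismatches`` permits a
    Hamming tolerance (no indels), 5'->3' sense strand only.
    """
    ff, rf = design.forward_flank, design.reverse_flank
    report = TrimReport()
    kept: list[tuple[str, str, str | None]] = []
    for rid, seq, qual in reads.records:
        f = _find_with_mismatches(seq, ff, 0, max_mismatches)
        if f < 0:
            report.discarded += 1
            continue
        region_start = f + len(ff)
        r = _find_with_mismatches(seq, rf, region_start, max_mismatches)
        if r < 0 or r - region_start != design.random_length:
            report.discarded += 1
            continue
        region = seq[region_start:r]
        q = qual[region_start:r] if qual is not None else None
        kept.append((rid, region, q))
        report.kept += 1
    return ReadSet(pool_id=reads.pool_id, records=kept), report


def count_pool(trimmed: ReadSet, total_reads: int | None = None) -> PoolCounts:
    """Collapse exact-duplicate random regions into abundance entries.

    Fractions and reads-per-million are computed over the trimmed reads.
    ``total_reads`` records the pre-trim read count (defaults to the
    trimmed count when trimming statistics are unavailable).
    """
    n = len(trimmed.records)
    if n == 0:
        raise ValueError("empty pool: no trimmed reads to count")
    lengths = {len(seq) for seq in trimmed.sequences()}
    if len(lengths) > 1:
        raise ValueError(f"trimmed reads have inconsistent lengths {sorted(lengths)}")
    counts = Counter(trimmed.sequences())
    entries = {
        seq: PoolEntry(sequence=seq, reads=r, fraction=r / n, rpm=r / n * 1e6)
        for seq, r in counts.items()
    }
    return PoolCounts(
        pool_id=trimmed.pool_id,
        total_reads=n if total_reads is None else total_reads,
        entries=entries,
    )


def family_fraction(pool: PoolCounts, motif: str) -> float:
    """Summed fraction of unique sequences containing ``motif``.

    The motif is matched as an exact substring at any offset, sense
    strand only.
    """
    lengths = {len(s) for s in pool.entries}
    if lengths and len(motif) > max(lengths):
        raise ValueError(
            f"motif ({len(motif)} nt) is longer than the random region "
            f"({max(lengths)} nt)"
        )
    return sum(e.fraction for s, e in pool.entries.items() if motif in s)


def combine_pools(pools: list[PoolCounts], weights: list[float] | None = None,
                  pool_id: str = "combined") -> PoolCounts:
    """Weighted mixture of pools on the fraction scale.

    Combined fraction of each sequence is sum_k w_k f_ik / sum_k w_k;
    equal weights model equimolar mixing of the pools.  Read counts in
    the result are weight-scaled and only meaningful as relative values;
    fractions and rpm are exact.
    """
    if not pools:
        raise ValueError("no pools to combine")
    if weights is None:
        weights = [1.0] * len(pools)
    if len(weights) != len(pools):
        raise ValueError("need one weight per pool")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    lengths = {len(s) for p in pools for s in p.entries}
    if len(lengths) > 1:
        raise ValueError(
            f"pools have mismatched random-region lengths {sorted(lengths)}"
        )
    wn = w / w.sum()
    frac: dict[str, float] = {}
    for wk, p in zip(wn, pools):
        if wk == 0:
            continue
        for seq, e in p.entries.items():
            frac[seq] = frac.get(seq, 0.0) + wk * e.fraction
    total = sum(p.trimmed_reads for p in pools)
    entries = {
        seq: PoolEntry(sequence=seq, reads=round(f * total),
                       fraction=f, rpm=f * 1e6)
        for seq, f in frac.items()
    }
    return PoolCounts(pool_id=pool_id, total_reads=total, entries=entries)


def pool_summary(pool: PoolCounts) -> PoolSummary:
    """5th/50th/95th percentiles of the per-unique-sequence fraction
    distribution, using linear interpolation between closest ranks."""
    fr = pool.fractions()
    if fr.size == 0:
        raise ValueError("empty pool")
    p5, p50, p95 = np.percentile(fr, [5, 50, 95], method="linear")
    return PoolSummary(
        percentiles={5: float(p5), 50: float(p50), 95: float(p95)},
        max_fraction=float(fr.max()),
        n_unique=int(fr.size),
    )


def enrichment_trajectory(
    pools: list[PoolCounts], motif: str
) -> FamilyTrajectory:
    """Family fraction and median sequence fraction per round, in order."""
    if not pools:
        raise ValueError("need at least one pool")
    per_round: dict[str, float] = {}
    medians: dict[str, float] = {}
    for p in pools:
        per_round[p.pool_id] = family_fraction(p, motif)
        medians[p.pool_id] = float(np.median(p.fractions()))
    return FamilyTrajectory(motif=motif, per_round=per_round, medians=medians)
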