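"""Shared readers and writers: FASTQ/FASTA, TSV tables, YAML configs.

All tabular output is tab-delimited UTF-8 with '.' decimal points and
floats at 6 significant digits, so golden files round-trip bit-exactly.
Sequence readers are gzip-transparent and streaming.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .pool import LibraryDesign, PoolCounts, ReadSet

__all__ = [
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "read_table",
    "write_table",
    "read_design",
    "write_pool_counts",
    "read_pool_counts",
    "write_trajectory",
]

FLOAT_FMT = "%.6g"


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_seqs(path: str | Path, fmt: str, pool_id: str | None) -> ReadSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pool_id is None:
        pool_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    records: list[tuple[str, str, str | None]] = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                qual = None
                if "phred_quality" in rec.letter_annotations:
                    qual = "".join(
                        chr(q + 33)
                        for q in rec.letter_annotations["phred_quality"]
                    )
                records.append((rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:
            raise ValueError(
                f"malformed {fmt.upper()} record #{len(records) + 1} "
                f"in {path}: {exc}"
            ) from exc
    return ReadSet(pool_id=pool_id, records=records)


def read_fastq(path: str | Path, pool_id: str | None = None) -> ReadSet:
    """Parse a (possibly gzipped) FASTQ file into a ReadSet."""
    return _read_seqs(path, "fastq", pool_id)


def read_fasta(path: str | Path, pool_id: str | None = None) -> ReadSet:
    """Parse a (possibly gzipped) FASTA file into a ReadSet."""
    return _read_seqs(path, "fasta", pool_id)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as FASTQ (gzipped when the path ends in .gz).

    Records lacking qualities get a constant Q30 placeholder.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for rid, seq, qual in reads.records:
            q = qual if qual is not None else "?" * len(seq)
            out.write(f"@{rid}\n{seq}\n+\n{q}\n")


def read_table(path: str | Path, required: list[str] | None = None
               ) -> pd.DataFrame:
    """Read a TSV table, checking that required columns are present.

    Extra columns are preserved as passthrough.
    """
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing column(s) {missing}; expected schema "
                f"includes {required}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV table with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_design(path: str | Path) -> LibraryDesign:
    """Load a library design from YAML (forward_flank, reverse_flank,
    random_length, total_length)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return LibraryDesign(
            forward_flank=cfg["forward_flank"],
            reverse_flank=cfg["reverse_flank"],
            random_length=int(cfg.get("random_length", 30)),
            total_length=int(cfg.get("total_length", 73)),
        )
    except KeyError as exc:
        raise ValueError(f"design file {path} missing key {exc}") from exc


def write_pool_counts(pool: PoolCounts, path: str | Path) -> None:
    """Ranked per-sequence abundance table: sequence, reads, fraction,
    rpm, rank."""
    rows = [
        {"sequence": e.sequence, "reads": e.reads, "fraction": e.fraction,
         "rpm": e.rpm, "rank": i + 1}
        for i, e in enumerate(pool.ranked())
    ]
    write_table(pd.DataFrame(rows), path)


def read_pool_counts(path: str | Path, pool_id: str | None = None
                     ) -> PoolCounts:
    """Load a pool-counts TSV back into a PoolCounts object."""
    from .pool import PoolEntry

    df = read_table(path, required=["sequence", "reads", "fraction", "rpm"])
    entries = {
        r.sequence: PoolEntry(sequence=r.sequence, reads=int(r.reads),
                              fraction=float(r.fraction), rpm=float(r.rpm))
        for r in df.itertuples()
    }
    total = int(df["reads"].sum())
    return PoolCounts(
        pool_id=pool_id or str(Path(path).stem),
        total_reads=total,
        entries=entries,
    )


def write_trajectory(trajectory, path: str | Path) -> None:
    """Family-trajectory table: round_id, family_fraction, median_fraction."""
    rows = [
        {"round_id": rid, "family_fraction": f,
         "median_fraction": trajectory.medians.get(rid, float("nan"))}
        for rid, f in trajectory.per_round.items()
    ]
    write_table(pd.DataFrame(rows), path)
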