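"""File I/O: FASTA/FASTQ reads and the intermediary match/mismatch files.

FASTA parsing goes through Biopython's SeqIO; qualities in FASTQ input
are ignored. The intermediary assignment files are the tab-separated
per-group *match*/*mismatch* record streams produced after the
comparison step: one file pair per group, carrying read ids and scores
only — sequences are re-attached after classification completes.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .scoring import MATCH, MISMATCH, MatchResult, Read

__all__ = [
    "read_fasta",
    "read_sequences",
    "write_fasta",
    "write_group_records",
    "read_group_records",
]

_TSV_HEADER = ["read_id", "group_id", "xi", "Xi", "strand", "status"]


def _format_of(path) -> str:
    suffix = Path(path).suffix.lower()
    return "fastq" if suffix in {".fastq", ".fq"} else "fasta"


def read_fasta(path) -> Iterator[Read]:
    """Yield reads from a FASTA (or FASTQ) file; id = first header token."""
    for record in SeqIO.parse(str(path), _format_of(path)):
        yield Read(record.id, str(record.seq))


def read_sequences(path) -> dict[str, str]:
    """Load a FASTA/FASTQ file into an id → sequence mapping."""
    return {r.read_id: r.sequence for r in read_fasta(path)}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_group_records(
    records_by_group: Mapping[str, Iterable[MatchResult]], out_dir
) -> dict[str, tuple[Path, Path]]:
    """Write per-group match/mismatch TSV file pairs.

    Columns: read_id, group_id, xi, Xi (4 decimals), strand, status.
    Returns group id → (match path, mismatch path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for gid, records in records_by_group.items():
        match_path = out_dir / f"{gid}.match.tsv"
        mismatch_path = out_dir / f"{gid}.mismatch.tsv"
        with open(match_path, "w", newline="") as mf, open(
            mismatch_path, "w", newline=""
        ) as mmf:
            wm = csv.writer(mf, delimiter="\t")
            wmm = csv.writer(mmf, delimiter="\t")
            wm.writerow(_TSV_HEADER)
            wmm.writerow(_TSV_HEADER)
            for rec in records:
                row = [
                    rec.read_id,
                    rec.group_id,
                    rec.xi,
                    f"{rec.Xi:.4f}",
                    rec.strand,
                    rec.status,
                ]
                (wm if rec.status == MATCH else wmm).writerow(row)
        paths[gid] = (match_path, mismatch_path)
    return paths


def read_group_records(records_dir) -> dict[str, list[MatchResult]]:
    """Read back the per-group record streams written by write_group_records."""
    records_dir = Path(records_dir)
    out: dict[str, list[MatchResult]] = {}
    for path in sorted(records_dir.glob("*.match.tsv")) + sorted(
        records_dir.glob("*.mismatch.tsv")
    ):
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                if row["status"] not in (MATCH, MISMATCH):
                    raise ValueError(f"{path}: bad status {row['status']!r}")
                rec = MatchResult(
                    row["read_id"],
                    row["group_id"],
                    int(row["xi"]),
                    float(row["Xi"]),
                    row["strand"],
                    0,
                    row["status"],
                )
                out.setdefault(rec.group_id, []).append(rec)
    return out
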