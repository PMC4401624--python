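"""Overlap-corrected match scoring of reads against group databases.

A read R is scanned with a 1-base sliding window; every k-mer found in
the group's database D_i raises the match score ξ by the number of its
bases not already counted. For consecutive database hits at genomic
offsets p < q the overlap is ob = max(k - q + p, 0), so each hit
contributes k - ob = min(k, q - p) new bases beyond the first hit's k.
Equivalently, ξ is the number of read bases covered by the union of
the matched k-mer intervals. The match rate Ξ = 100·ξ/len(R) is
compared against the match cut-off MC to label the read *match* or
*mismatch* for the group.

Both the read and its reverse complement are scored; the strand with
the larger ξ is kept (forward on ties), strands are never summed.
An optional k'-stride prefilter probes only every k'-th window and
skips full scoring of a strand with no sampled hit — a speed heuristic
that can drop true matches; k' = 1 disables it.

Windows containing non-ACGT symbols are skipped, but hit positions
remain genomic offsets, so the inter-hit distance q - p in the overlap
formula counts skipped windows too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .database import KmerDatabase
from .encoding import encode_windows, reverse_complement

__all__ = [
    "Read",
    "MatchResult",
    "match_score_strand",
    "match_rate",
    "prefilter",
    "score_read_against_group",
    "compare_read_set",
]

FORWARD = "forward"
REVERSE = "reverse"
MATCH = "match"
MISMATCH = "mismatch"


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read id must be nonempty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchResult:
    """Score of one read against one group, best strand retained."""

    read_id: str
    group_id: str
    xi: int
    Xi: float
    strand: str
    matched_kmer_count: int
    status: str  # MATCH iff Xi >= MC at scoring time


def _score_positions(positions: np.ndarray, k: int) -> int:
    """ξ from sorted genomic hit offsets: k for the first hit, then
    min(k, gap) per subsequent hit."""
    if positions.size == 0:
        return 0
    gaps = np.diff(positions)
    return int(k + np.minimum(gaps, k).sum())


def match_score_strand(
    sequence: str, db: KmerDatabase
) -> tuple[int, int, np.ndarray]:
    """Score one strand: returns (ξ, matched k-mer count, hit offsets)."""
    positions, values = encode_windows(sequence, db.k)
    if positions.size == 0:
        return 0, 0, positions
    hits = db.contains_many(values)
    hit_pos = positions[hits]
    return _score_positions(hit_pos, db.k), int(hit_pos.size), hit_pos


def match_rate(xi: int, read_length: int) -> float:
    """Ξ = 100·ξ/len(R), defined as 0 for an empty read."""
    if read_length <= 0:
        return 0.0
    return 100.0 * xi / read_length


def prefilter(sequence: str, db: KmerDatabase, kprime: int) -> bool:
    """k'-stride screen: does any k-mer at offsets 0, k', 2k', ... hit?

    k' = 1 means no filtering (always True). Offsets falling on
    skipped (non-ACGT) windows simply cannot hit.
    """
    if not 1 <= kprime <= db.k:
        raise ValueError(f"k'={kprime} outside [1, k={db.k}]")
    if kprime == 1:
        return True
    positions, values = encode_windows(sequence, db.k)
    if positions.size == 0:
        return False
    sampled = positions % kprime == 0
    if not sampled.any():
        return False
    return bool(db.contains_many(values[sampled]).any())


def score_read_against_group(
    read: Read, db: KmerDatabase, mc: float, kprime: int = 1
) -> MatchResult:
    """Best-strand match score of ``read`` against one group database.

    Each strand is prefiltered and scored independently; the strand
    with larger ξ wins, forward on a tie. The result is labelled
    *match* when Ξ >= MC.
    """
    best_xi, best_count, best_strand = 0, 0, FORWARD
    for strand, seq in (
        (FORWARD, read.sequence),
        (REVERSE, reverse_complement(read.sequence)),
    ):
        if not prefilter(seq, db, kprime):
            continue
        xi, count, _ = match_score_strand(seq, db)
        if xi > best_xi:
            best_xi, best_count, best_strand = xi, count, strand
    Xi = match_rate(best_xi, len(read))
    status = MATCH if Xi >= mc else MISMATCH
    return MatchResult(read.read_id, db.group_id, best_xi, Xi, best_strand, best_count, status)


def compare_read_set(
    reads: Sequence[Read],
    databases: Iterable[KmerDatabase],
    mc: float,
    kprime: int = 1,
) -> dict[str, list[MatchResult]]:
    """Score every read against every group, one database at a time.

    Databases are iterated in the outer loop so at most one group's
    index need be resident at once (pass a lazy iterable to exploit
    this). Returns, per group id, the full result list — each (read,
    group) pair appears exactly once, as *match* or *mismatch*.
    Duplicate read ids are rejected at ingest.
    """
    reads = list(reads)
    seen: set[str] = set()
    for r in reads:
        if r.read_id in seen:
            raise ValueError(f"duplicate read id {r.read_id!r}")
        seen.add(r.read_id)
    out: dict[str, list[MatchResult]] = {}
    for db in databases:
        if db.group_id in out:
            raise ValueError(f"duplicate group id {db.group_id!r}")
        out[db.group_id] = [
            score_read_against_group(r, db, mc, kprime) for r in reads
        ]
    return out
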