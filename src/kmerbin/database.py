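"""Unique-k-mer database of one reference group: build, serialize, query.

A group database holds the set of all k-mers occurring at least once in
the group's reference sequences, deduplicated and kept sorted (packed
2-bit codes sort lexicographically, see :mod:`kmerbin.encoding`). Two
representations exist:

* the **compact** on-disk form: k-mers sharing a 4-nt prefix are broken
  into prefix + suffix, the prefix written once per block followed by
  the packed suffixes (2(k-4) bits each, padded to whole bytes) and
  their occurrence counts — see ``docs/file_format.md`` for the byte
  layout;
* the **loaded** in-memory form: a flat sorted uint64 array plus, for
  k >= 10, the classification index — 65,536 (= 4^8) bucket offsets
  keyed by the 8-nt prefix, so a membership probe binary-searches only
  the bucket of its top 16 bits.

Occurrence counts are carried through the file format but never
consulted by queries: classification needs presence only.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .encoding import MAX_K, encode_windows

__all__ = [
    "MIN_K",
    "MIN_INDEXED_K",
    "PREFIX_BUCKETS",
    "KmerDatabase",
    "DatabaseFormatError",
    "build_database",
    "build_classification_index",
    "save_compact",
    "load_compact",
    "contains",
]

logger = logging.getLogger(__name__)

#: Smallest supported k: the compact format cuts a 4-nt prefix.
MIN_K = 5
#: Smallest k for which the 8-nt-prefix classification index exists.
MIN_INDEXED_K = 10
#: Number of buckets in the classification index: 4^8 8-nt prefixes.
PREFIX_BUCKETS = 4**8

_MAGIC = b"KMRBINDB"
_VERSION = 1


class DatabaseFormatError(ValueError):
    """Raised when a compact database file is malformed or truncated."""


@dataclass
class KmerDatabase:
    """Sorted unique k-mer set of one reference group.

    ``kmers`` is strictly increasing (uint64 packed codes); ``counts``,
    when present, gives each k-mer's occurrence count across the
    group's sequences; ``prefix_index`` is the classification index
    (``PREFIX_BUCKETS`` bucket-start offsets) or ``None`` if not built.
    """

    k: int
    group_id: str
    kmers: np.ndarray
    counts: np.ndarray | None = None
    prefix_index: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not MIN_K <= self.k <= MAX_K:
            raise ValueError(f"k={self.k} outside supported range [{MIN_K}, {MAX_K}]")
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerDatabase):
            return NotImplemented
        return (
            self.k == other.k
            and self.group_id == other.group_id
            and np.array_equal(self.kmers, other.kmers)
        )

    def bucket_bounds(self, bucket: int) -> tuple[int, int]:
        """Half-open [start, end) span of ``bucket`` in the sorted array."""
        if self.prefix_index is None:
            raise ValueError("classification index not built")
        start = int(self.prefix_index[bucket])
        end = (
            int(self.prefix_index[bucket + 1])
            if bucket + 1 < PREFIX_BUCKETS
            else len(self)
        )
        return start, end

    def contains_many(self, values: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of packed k-mers.

        Binary search over the sorted array; buckets being contiguous
        slices of it, the answer is identical to a per-bucket search.
        """
        values = np.asarray(values, dtype=np.uint64)
        if self.kmers.size == 0 or values.size == 0:
            return np.zeros(values.shape, dtype=bool)
        idx = np.searchsorted(self.kmers, values)
        inside = idx < self.kmers.size
        hits = np.zeros(values.shape, dtype=bool)
        hits[inside] = self.kmers[idx[inside]] == values[inside]
        return hits


def build_database(
    sequences: Iterable[str], k: int, group_id: str, with_index: bool = True
) -> KmerDatabase:
    """Collect, sort and deduplicate the k-mers of a group's sequences.

    Every k-length window containing only A/C/G/T contributes; windows
    with N or other ambiguity codes are skipped. An empty sequence
    collection is rejected; sequences all shorter than k produce a
    valid empty database (logged as a warning). The classification
    index is built automatically when k allows it.
    """
    chunks = []
    n_seqs = 0
    for seq in sequences:
        n_seqs += 1
        _, values = encode_windows(seq, k)
        if values.size:
            chunks.append(values)
    if n_seqs == 0:
        raise ValueError("cannot build a database from an empty sequence collection")
    if chunks:
        allk = np.concatenate(chunks)
        kmers, counts = np.unique(allk, return_counts=True)
    else:
        logger.warning(
            "group %s: no sequence yields a %d-mer; database is empty", group_id, k
        )
        kmers = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    db = KmerDatabase(k=k, group_id=group_id, kmers=kmers, counts=counts)
    if with_index and k >= MIN_INDEXED_K:
        build_classification_index(db)
    return db


def build_classification_index(db: KmerDatabase) -> np.ndarray:
    """Build the 65,536-bucket prefix index of ``db`` in place.

    Bucket ``b`` spans the k-mers whose top 16 bits (8-nt prefix)
    equal ``b``; the index stores each bucket's start offset into the
    sorted array. Requires k >= 10 so that an 8-nt prefix leaves a
    non-empty suffix.
    """
    if db.k < MIN_INDEXED_K:
        raise ValueError(
            f"classification index needs k >= {MIN_INDEXED_K}, got k={db.k}"
        )
    shift = np.uint64(2 * (db.k - 8))
    prefixes = db.kmers >> shift
    starts = np.searchsorted(
        prefixes, np.arange(PREFIX_BUCKETS, dtype=np.uint64), side="left"
    ).astype(np.int64)
    db.prefix_index = starts
    return starts


def contains(db: KmerDatabase, value: int, k: int | None = None) -> bool:
    """Membership of one packed k-mer, via the prefix index when present.

    ``k``, if given, must equal the database's k (a probe of a
    different length can never be meaningful and is rejected).
    """
    if k is not None and k != db.k:
        raise ValueError(f"probe k={k} does not match database k={db.k}")
    if db.kmers.size == 0:
        return False
    if not 0 <= value < 4**db.k:
        raise ValueError(f"value {value} not a valid {db.k}-mer code")
    if db.prefix_index is not None:
        bucket = value >> (2 * (db.k - 8))
        lo, hi = db.bucket_bounds(int(bucket))
    else:
        lo, hi = 0, len(db)
    i = int(np.searchsorted(db.kmers[lo:hi], np.uint64(value))) + lo
    return i < hi and int(db.kmers[i]) == value


# ---------------------------------------------------------------------------
# Compact on-disk format (little-endian throughout; layout in docs)
# ---------------------------------------------------------------------------

def _suffix_bytes(k: int) -> int:
    return (2 * (k - 4) + 7) // 8


def save_compact(db: KmerDatabase, path) -> None:
    """Write ``db`` in the compact prefix-block format.

    Header, then one block per occupied 4-nt prefix: prefix code,
    suffix count, the packed sorted suffixes, their occurrence counts.
    """
    gid = db.group_id.encode("utf-8")
    sbytes = _suffix_bytes(db.k)
    shift = np.uint64(2 * (db.k - 4))
    mask = np.uint64((1 << (2 * (db.k - 4))) - 1)
    try:
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<BBH", _VERSION, db.k, len(gid)))
            fh.write(gid)
            fh.write(struct.pack("<Q", len(db)))
            if len(db) == 0:
                return
            prefixes = (db.kmers >> shift).astype(np.uint16)
            suffixes = db.kmers & mask
            counts = (
                db.counts
                if db.counts is not None
                else np.ones(len(db), dtype=np.int64)
            )
            boundaries = np.flatnonzero(np.diff(prefixes)) + 1
            starts = np.concatenate(([0], boundaries, [len(db)]))
            for s, e in zip(starts[:-1], starts[1:]):
                fh.write(struct.pack("<BQ", int(prefixes[s]), int(e - s)))
                block = suffixes[s:e].astype("<u8").view(np.uint8).reshape(-1, 8)
                fh.write(block[:, :sbytes].tobytes())
                fh.write(np.asarray(counts[s:e], dtype="<u4").tobytes())
    except OSError as exc:
        raise OSError(f"cannot write compact database to {path}: {exc}") from exc


def load_compact(path) -> KmerDatabase:
    """Read a compact database file back into the loaded in-memory form.

    Verifies magic and version, reconstructs the sorted k-mer array
    bit-exactly, and builds the classification index when k >= 10.
    """
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise OSError(f"cannot read compact database from {path}: {exc}") from exc
    buf = io.BytesIO(data)

    def take(n: int, what: str) -> bytes:
        chunk = buf.read(n)
        if len(chunk) != n:
            raise DatabaseFormatError(f"{path}: truncated while reading {what}")
        return chunk

    if take(8, "magic") != _MAGIC:
        raise DatabaseFormatError(f"{path}: not a compact k-mer database (bad magic)")
    version, k, gid_len = struct.unpack("<BBH", take(4, "header"))
    if version != _VERSION:
        raise DatabaseFormatError(f"{path}: unsupported format version {version}")
    if not MIN_K <= k <= MAX_K:
        raise DatabaseFormatError(f"{path}: invalid k={k} in header")
    group_id = take(gid_len, "group id").decode("utf-8")
    (total,) = struct.unpack("<Q", take(8, "k-mer count"))
    sbytes = _suffix_bytes(k)
    shift = np.uint64(2 * (k - 4))
    kmer_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []
    seen = 0
    while seen < total:
        prefix, n = struct.unpack("<BQ", take(9, "prefix block header"))
        raw = np.frombuffer(take(int(n) * sbytes, "suffixes"), dtype=np.uint8)
        padded = np.zeros((int(n), 8), dtype=np.uint8)
        padded[:, :sbytes] = raw.reshape(int(n), sbytes)
        suffixes = padded.view("<u8").ravel().astype(np.uint64)
        kmer_chunks.append((np.uint64(prefix) << shift) | suffixes)
        count_chunks.append(
            np.frombuffer(take(int(n) * 4, "occurrence counts"), dtype="<u4").astype(
                np.int64
            )
        )
        seen += int(n)
    if seen != total:
        raise DatabaseFormatError(f"{path}: block k-mer total {seen} != header {total}")
    kmers = (
        np.concatenate(kmer_chunks) if kmer_chunks else np.empty(0, dtype=np.uint64)
    )
    counts = (
        np.concatenate(count_chunks) if count_chunks else np.empty(0, dtype=np.int64)
    )
    db = KmerDatabase(k=k, group_id=group_id, kmers=kmers, counts=counts)
    if k >= MIN_INDEXED_K:
        build_classification_index(db)
    return db
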