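"""2-bit nucleotide encoding and k-mer extraction.

Every k-mer over {A, C, G, T} is packed into a single unsigned integer,
two bits per base, most-significant base first, with the code

    A = 0, C = 1, G = 2, T = 3.

Because the base code is ordered like the alphabet and the leftmost base
occupies the highest bits, integer comparison of packed values coincides
with lexicographic comparison of the strings — the property that lets a
sorted array of packed k-mers serve as a lexicographically sorted k-mer
list. With the packed value confined to 64 bits this supports k up to 31.

Windows containing any symbol outside {A, C, G, T} (N or any other IUPAC
ambiguity code, any case) are skipped during extraction; their genomic
positions are preserved, i.e. positions of the surviving windows are
offsets into the original sequence.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MAX_K",
    "encode_kmer",
    "decode_kmer",
    "encode_windows",
    "extract_kmers",
    "reverse_complement",
]

#: Largest supported k-mer length: 2k bits must fit in a 64-bit word.
MAX_K = 31

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# 256-entry lookup: byte of an ASCII nucleotide -> 2-bit code, -1 for
# anything that is not an unambiguous base (N, IUPAC codes, gaps, ...).
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c

_COMPLEMENT = bytes.maketrans(
    b"ACGTacgt", b"TGCAtgca"
)


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into its 2-bit integer code.

    Raises ``ValueError`` naming the first offending position if the
    string contains a symbol outside {A, C, G, T} (case-insensitive),
    or if its length exceeds the 64-bit limit (k > 31) or is zero.
    """
    k = len(kmer)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k-mer length {k} outside supported range [1, {MAX_K}]")
    value = 0
    for i, base in enumerate(kmer):
        code = _BASE_CODE.get(base.upper())
        if code is None:
            raise ValueError(
                f"non-ACGT symbol {base!r} at position {i} in k-mer {kmer!r}"
            )
        value = (value << 2) | code
    return value


def decode_kmer(value: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`: unpack ``value`` into a k-length string."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k-mer length {k} outside supported range [1, {MAX_K}]")
    if not 0 <= value < 4**k:
        raise ValueError(f"value {value} not a valid {k}-mer code")
    bases = []
    for shift in range(2 * (k - 1), -1, -2):
        bases.append(_CODE_BASE[(value >> shift) & 3])
    return "".join(bases)


def sequence_codes(sequence: str) -> np.ndarray:
    """Per-base 2-bit codes of ``sequence`` as int8, -1 for non-ACGT symbols."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def encode_windows(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode every valid k-length window of ``sequence``.

    Returns ``(positions, values)``: 0-based genomic offsets of the
    windows consisting solely of A/C/G/T, and their packed codes
    (uint64), in left-to-right order. A sequence shorter than k yields
    two empty arrays.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k-mer length {k} outside supported range [1, {MAX_K}]")
    codes = sequence_codes(sequence)
    n = codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64))
    # A window is valid iff it covers no negative code.
    bad = np.concatenate(([0], np.cumsum(codes < 0)))
    valid = (bad[k:] - bad[:-k]) == 0
    windows = np.lib.stride_tricks.sliding_window_view(
        np.where(codes < 0, 0, codes).astype(np.int64), k
    )
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    values = windows @ powers  # max 4^31-1 < 2^63, no overflow
    positions = np.nonzero(valid)[0].astype(np.int64)
    return positions, values[positions].astype(np.uint64)


def extract_kmers(sequence: str, k: int) -> list[tuple[int, int]]:
    """All valid k-mers of ``sequence`` as ``(position, packed value)`` pairs."""
    positions, values = encode_windows(sequence, k)
    return list(zip(positions.tolist(), values.tolist()))


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement; any ambiguity symbol becomes N.

    An involution on {A, C, G, T, N} strings (case preserved for the
    four unambiguous bases).
    """
    comp = sequence.encode("ascii", errors="replace").translate(_COMPLEMENT)
    out = bytearray(comp)
    for i, b in enumerate(out):
        if chr(b).upper() not in "ACGT":
            out[i] = ord("N")
    return bytes(out[::-1]).decode("ascii")
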