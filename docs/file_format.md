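# Compact k-mer database format

Little-endian throughout. One file per reference group.

## Header

| offset | size | field |
|-------:|-----:|-------|
| 0      | 8    | magic `KMRBINDB` |
| 8      | 1    | format version, currently 1 |
| 9      | 1    | k (k-mer length in bases, 5–31) |
| 10     | 2    | group-id length `L` (uint16) |
| 12     | L    | group id, UTF-8 |
| 12+L   | 8    | total k-mer count (uint64) |

A database with zero k-mers ends after the header.

## Prefix blocks

The sorted k-mers are split into their 4-nt prefix (top 8 bits of the
packed code) and a 2(k−4)-bit suffix. For each *occupied* prefix, in
ascending prefix order:

| size | field |
|-----:|-------|
| 1    | prefix code (uint8) |
| 8    | suffix count `n` (uint64) |
| n·ceil(2(k−4)/8) | packed suffixes, ascending, each right-aligned in ceil(2(k−4)/8) little-endian bytes |
| n·4  | per-suffix occurrence counts (uint32) |

At most 256 blocks exist (4⁴ prefixes); unoccupied prefixes are
absent. Suffixes within a block are strictly increasing, so
concatenating `(prefix << 2(k−4)) | suffix` over all blocks reproduces
the sorted unique k-mer array exactly.

Occurrence counts record how often each k-mer appeared across the
group's sequences. They are written for format completeness and read
back, but queries never consult them: classification needs presence
only.

## Loaded (non-compact) form

Loading rebuilds the flat sorted uint64 array and, for k ≥ 10, the
classification index: 65,536 (= 4⁸) bucket start offsets keyed by each
k-mer's 8-nt prefix (top 16 bits). Bucket b spans
`[index[b], index[b+1])` (the last bucket ends at the array length), so
a membership probe binary-searches only its bucket. For 5 ≤ k < 10 an
8-nt prefix would leave no suffix; such databases are queried by
binary search over the whole array and carry no index.
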