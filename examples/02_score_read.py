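"""Score a read against a reference group with the cumulative match score.

A 14-nt read whose first 12 nt occur verbatim in the reference is
scanned with a 1-base sliding window at k = 5. Its eight leading
5-mer windows all hit the database; each hit after the first adds
only its non-overlapping base, so the covered stretch of 12 bases
yields match score ξ = 12 and match rate Ξ = 12/14 · 100% = 85.7%.
"""

import kmerbin as kb
from kmerbin.encoding import encode_windows

reference = "ACGGTCAGGTTAAGGTCGGGAATTCTGCATT"
db = kb.build_database([reference], k=5, group_id="S")

stem = reference[3:15]  # 12 nt taken verbatim from the reference
# pick a 2-nt tail whose two rightmost 5-mer windows miss the database
read = next(
    stem + a + b
    for a in "ACGT"
    for b in "ACGT"
    if not db.contains_many(encode_windows(stem + a + b, 5)[1])[8:].any()
)

result = kb.score_read_against_group(kb.Read("sample", read), db, mc=30.0)
print(f"read            : {read} ({len(read)} nt)")
print(f"match score xi  : {result.xi} bases covered by shared 5-mers")
print(f"match rate Xi   : {result.Xi:.1f} %")
print(f"strand          : {result.strand}")
print(f"matched 5-mers  : {result.matched_kmer_count}")
print(f"status at MC=30 : {result.status}")
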