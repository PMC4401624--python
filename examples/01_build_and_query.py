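"""Build a group's unique-k-mer database, serialize it, query membership.

Every 15-mer of the reference that consists only of A/C/G/T is packed
into a 2-bit-per-base integer, deduplicated and kept sorted; the
compact file stores prefix-sharing k-mers as one 4-nt prefix plus a
list of suffixes. Membership probes go through the 65,536-bucket
prefix index built on load.
"""

import tempfile
from pathlib import Path

import numpy as np

import kmerbin as kb

rng = np.random.default_rng(42)
reference = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2_000))

db = kb.build_database([reference], k=15, group_id="demo_group")
print(f"reference length : {len(reference)} nt")
print(f"unique 15-mers   : {len(db)}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.kdb"
    kb.save_compact(db, path)
    print(f"compact file     : {path.stat().st_size} bytes")
    loaded = kb.load_compact(path)
    print(f"round trip equal : {loaded == db}")
    print(f"index buckets    : {len(loaded.prefix_index)}")

present = kb.encode_kmer(reference[100:115])
absent = kb.encode_kmer("A" * 15)
print(f"reference 15-mer present: {kb.contains(db, present)}")
print(f"poly-A 15-mer present   : {kb.contains(db, absent)}")

# The counts: a k-mer database answers presence only — one copy per
# distinct k-mer regardless of how often it occurs in the group.
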