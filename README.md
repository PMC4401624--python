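# kmerbin

Taxonomic binning of metagenomic reads against indexed unique-k-mer
databases of reference groups, with an overlap-corrected match score and
iterative top-down classification along a taxonomy tree.

## The problem

A shotgun metagenomic run yields short reads from an unknown mixture of
organisms. Taxonomy-dependent binning assigns each read to a taxon by
comparing it with grouped reference sequences — here, a *group* G_i is
the set of reference sequences belonging to one taxon at a rank (all
Proteobacteria genomes, say). kmerbin is for people who want that
pipeline as an importable, fully testable Python library with a
self-contained synthetic benchmark: reference grouping, k-mer indexing,
scoring, assignment, tree descent and evaluation metrics, end to end.

## The method

**Database.** Each group's sequences are cut into overlapping k-mers
(1-base sliding window; windows containing N or any other ambiguity
symbol are skipped). The k-mers are 2-bit packed (A=0, C=1, G=2, T=3,
most-significant base first, so integer order is lexicographic order),
deduplicated and sorted. On disk, k-mers sharing a 4-nt prefix are
stored as the prefix plus a suffix list; in memory a classification
index of 65,536 (= 4⁸) bucket offsets keyed by the 8-nt prefix makes a
membership probe a binary search within one bucket.

**Scoring.** For a read R and group database D_i, every k-mer of R is
looked up in D_i. The match score ξ accumulates, per hit, the number of
bases not already counted: for consecutive hits at offsets p < q the
overlap is ob = max(k − q + p, 0), so the hit adds k − ob bases.
Equivalently ξ is the number of read bases covered by the union of
matched k-mer windows. The match rate Ξ = 100·ξ/|R| is compared with a
match cut-off MC: Ξ ≥ MC puts the read in the group's *match* file,
otherwise the *mismatch* file. Both the read and its reverse complement
are scored; the better strand counts. An optional k′-stride prefilter
skips full scoring of strands with no sampled hit (k′ = 1 disables it).

**Assignment.** A read goes to the group with the highest ξ among its
*match* records; if there are none, the best *mismatch* record may win
provided it contains at least one whole k-mer (ξ ≥ k). Ties are broken
by policy: `all` (multi-assignment), `first` (deterministic), `random`
(seeded), or `none` (ties disqualify). Reads meeting no criterion are
NC (not classified).

**Tree descent.** Classification starts at a high rank (phylum by
default) and descends: the reads assigned to group G_b at rank j are
re-classified against only the subgroups of G_b at rank j+1, so each
level's input files are exactly the previous level's outputs. NC reads
stop; a branch with no subgroups keeps its parent label.

**Metrics.** Over a labelled read set, Classified = 100·(TP+FP)/all,
Sensitivity = 100·TP/all, Precision = 100·TP/(TP+FP).

## Worked example

`examples/02_score_read.py` builds a k = 5 database from one reference
sequence and scores a 14-nt read whose first 12 nt occur verbatim in
the reference while its last two 5-mer windows miss:

```
read            : GTCAGGTTAAGGAA (14 nt)
match score xi  : 12 bases covered by shared 5-mers
match rate Xi   : 85.7 %
strand          : forward
matched 5-mers  : 8
status at MC=30 : match
```

Eight consecutive window hits cover 5 + 7·1 = 12 bases, so ξ = 12 and
Ξ = 12/14·100% = 85.7%; at MC = 30% the read is pre-assigned to the
group. The other examples build and serialize a database
(`01_build_and_query.py`), run the full two-rank descent on a synthetic
community (`03_taxonomy_descent.py`), and show sensitivity decaying as
the simulated substitution rate rises (`04_simulate_and_evaluate.py`).

## Command line

The `kmerbin` console script wraps the library: `build` (group
database), `compare` (per-group match/mismatch records), `assign`
(best-group files + NC), `tree` (full descent from a YAML config),
`simulate` (labelled fixture) and `evaluate` (metrics). Each command is
a thin shell over the functions above.

## Layout

- `src/kmerbin/` — encoding, database, taxonomy, scoring, assignment,
  tree, simulate, metrics, io, cli
- `docs/methods.md` — models, parameters, numerical choices, limits
- `docs/file_format.md` — compact database byte layout
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end acceptance tests
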