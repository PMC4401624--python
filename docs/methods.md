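# Methods

## Model and procedure

kmerbin classifies metagenomic reads by exact shared k-mer content.
The reference sequences are partitioned into groups — one group per
taxon at a rank, with optional *special groups* (subtree roots such as
Viruses/Viroids whose sequences always form their own group). Each
group yields a database D_i: the set of k-mers occurring at least once
in its sequences, deduplicated and sorted. The similarity of a read R
to a group is the match score

ξ = Σ_j ξ_j, ξ_j = k − ob_j,

summed over the read's k-mers found in D_i in left-to-right order,
where ob_j = max(k − q + p, 0) is the overlap in bases between the
j-th hit (offset q) and the previous hit (offset p). This makes ξ the
size of the union of matched k-mer intervals: a read covered end to
end scores its full length, and a single isolated hit scores k. The
match rate Ξ = 100·ξ/|R| normalises by read length, and a cut-off MC
splits each group's records into *match* (Ξ ≥ MC) and *mismatch*
streams. Assignment takes the argmax of ξ over the match records,
falling back (when enabled) to mismatch records with ξ ≥ k — a read
with at least one whole matching k-mer can still be placed even below
MC, which raises sensitivity substantially at little precision cost.
Classification then descends the taxonomy: reads assigned to a group
at rank j are re-classified against that group's subgroups at rank
j+1, so the comparison space shrinks along each branch instead of
growing with the whole reference set.

Assumptions worth stating: matching is exact and substitution-only —
an indel shifts all downstream k-mers and is not modelled; both
strands are scored independently and never summed; reference k-mers
are stored as they appear on the forward strand (no canonical k-mers —
the read's reverse complement is scored instead).

## Parameters

| parameter | default | meaning |
|----------|---------|---------|
| k | 21 (supported 5–31) | k-mer length in bases. Short k raises sensitivity on divergent reads but admits chance matches; long k does the opposite. 15–30 is the practical band for real references; the 64-bit packed code caps k at 31, and the compact format's 4-nt prefix needs k ≥ 5. |
| MC | 30 (%) | match cut-off on Ξ. "Match" status means Ξ ≥ MC (the comparison is inclusive). Can be overridden per rank in a tree run. |
| k′ | 1 | prefilter stride: probe k-mers at offsets 0, k′, 2k′, … and skip full scoring of a strand with no sampled hit. A speed heuristic that can drop true matches, hence off (1) by default; applied per strand. |
| tie policy | all | `all` (every tied group), `first` (smallest group id — the deterministic reading of "any group"), `random` (seeded), `none` (tie ⇒ NC; the counting convention that keeps per-group tallies honest in single-assignment evaluations). |
| use_mismatch | on | admit mismatch records with ξ ≥ k when no match record exists. |
| rank path | phylum → class → order → family → genus | descent order; the synthetic fixtures use the two-rank path phylum → genus. |

## Synthetic data

`simulate_fixture` emulates a small community with known truth: a
three-level taxonomy (root, phyla, leaf taxa), one i.i.d.-uniform ACGT
genome per leaf, and reads drawn uniformly over leaves, genome
positions and strands, then corrupted by per-base substitutions
(uniform among the three other bases) and optional N injection. Truth
at any rank is derived from the source leaf through the taxonomy, never
stored separately. Defaults — 2 phyla × 2 genera, 100 kb genomes,
10,000 reads of 150 nt, 1% substitutions — are the study conditions the
test suite measures under; smaller copies of the same design appear
where a test only needs structure, not statistics.

What uniform genomes do **not** model: repeats, GC/composition bias,
shared homology between taxa, platform error profiles (homopolymer or
quality-dependent errors) and indels, and skewed community abundances.
Passing the recovery tests therefore shows the pipeline is correct and
self-consistent, not that it attains any particular accuracy on real
communities, where inter-genome similarity is the binding constraint.
A read-filter utility drops reads with more than 50% unknown bases
(threshold configurable), the usual pre-filter for heavily masked
datasets.

## Numerical and design choices

- **Encoding.** A=0 < C=1 < G=2 < T=3, most-significant base first:
  packed integers sort like strings, so one sorted uint64 array is both
  the set and its lexicographic order. Lowercase is accepted; every
  non-ACGT symbol (N and all other IUPAC codes) invalidates the windows
  covering it.
- **Skipped windows and distances.** Hit offsets are genomic, so the
  q − p in the overlap formula counts skipped (ambiguous) windows too;
  the interval-union identity survives Ns.
- **Index.** 65,536 bucket start offsets (8-nt prefix, top 16 bits).
  Built for k ≥ 10; below that the whole-array binary search is used.
  An 8-nt-prefix suffix does not generally fit one byte (k − 8 > 4
  bases for the k values of interest), so suffixes are held unpacked in
  the sorted uint64 array in memory and packed to ceil(2(k−4)/8) bytes
  only on disk.
- **Strand tie.** Equal forward/reverse ξ keeps forward. Strands are
  prefiltered and scored independently; per-read overlap state resets
  between groups and strands.
- **Determinism.** Every stochastic step (fixture generation, random
  tie-break) flows from one seed; identical inputs and seed give
  byte-identical outputs, including the intermediary files.
- **Degenerate inputs.** Reads shorter than k score 0 (not an error);
  zero-length reads have Ξ = 0; an empty database answers no; a group
  whose sequences are all shorter than k builds an empty database with
  a warning.
- **Descent semantics.** Under multi-assignment a read tied across
  parents descends each branch independently with per-branch
  provenance; a winning group with no subgroups terminates its branch
  and the deepest assignment is the read's final label.
- **Evaluation convention.** A read whose descent stopped above the
  evaluated rank counts as unclassified at that rank, never as
  correct.

## Problem sizes

The test suite runs entirely on generated data: property tests use
reads ≤ 150 nt against single-reference databases across
k ∈ {10, 15, 21, 30}; serialization is checked on 100 random databases;
the end-to-end recovery test uses the full default fixture (4 taxa ×
100 kb, 10,000 reads), which classifies in well under a minute on one
CPU. These sizes exercise every code path at desk scale; the data
structures (sorted arrays + prefix buckets) are the same ones that
scale to genome-database-sized groups, where construction would want
external sorting that this package deliberately leaves out.

## Known limitations

- Substitution-only similarity: indels break the shared-k-mer chain.
- The k′ prefilter is unsound by design (documented speed/recall
  trade); results with k′ > 1 are not guaranteed identical to full
  scoring.
- In-memory database construction only; no abundance queries (the
  stored occurrence counts are format payload, not an API).
- Name-based taxon resolution and NCBI merged/deleted-node handling
  are out of scope; the dump parsers cover the id-based core dialect.
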