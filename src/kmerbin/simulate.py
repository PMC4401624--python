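"""Self-contained synthetic fixtures: taxonomy, genomes, labelled reads.

The generator emulates a small shotgun-metagenomics study with known
ground truth: a 2–4 rank taxonomy (root / phyla / genera by default),
one i.i.d.-uniform ACGT genome per leaf taxon, and reads drawn
uniformly from the genomes and strands, corrupted with per-base
substitution errors and, optionally, unknown-base (N) injection. The
truth label of a read at any rank is derived from its source leaf
taxon through the taxonomy — a single source of truth.

Defaults mirror the study conditions used throughout the test suite:
4 leaf taxa (2 phyla × 2 genera), 100 kb genomes, 10,000 reads of
150 nt, substitution rate 1%. Everything is reproducible: the same
parameters and seed regenerate the fixture bit-for-bit.

Uniform genomes carry no repeats, composition bias or shared homology
between taxa, so they exercise correctness, not real-data hardness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import reverse_complement
from .scoring import Read
from .taxonomy import TaxonNode, TaxonomyTree, ancestor_at_rank

__all__ = [
    "FixtureParams",
    "SyntheticFixture",
    "simulate_fixture",
    "write_fixture",
    "filter_ambiguous_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureParams:
    n_phyla: int = 2
    genera_per_phylum: int = 2
    genome_length: int = 100_000
    n_reads: int = 10_000
    read_length: int = 150
    substitution_rate: float = 0.01
    n_injection_rate: float = 0.0
    rank_names: Sequence[str] = ("phylum", "genus")

    def validate(self) -> None:
        if self.n_phyla * self.genera_per_phylum < 2:
            raise ValueError("need at least 2 leaf taxa")
        if self.read_length > self.genome_length:
            raise ValueError("read longer than genome")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome must be at least 10 read lengths long")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")
        if not 0 <= self.n_injection_rate < 1:
            raise ValueError("N-injection rate must be in [0, 1)")
        if len(self.rank_names) != 2:
            raise ValueError("rank_names must name the phylum- and leaf-level ranks")


@dataclass
class SyntheticFixture:
    tree: TaxonomyTree
    genomes: dict[int, str]              # leaf taxon id -> genome
    reads: list[Read]
    truth: dict[str, dict[str, int]]     # read id -> rank -> taxon id
    seq_taxon_map: dict[str, int]        # reference sequence id -> leaf taxon
    sequences: dict[str, str]            # reference sequence id -> genome
    params: FixtureParams = field(default_factory=FixtureParams)
    seed: int = 0


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, n_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if sub_rate > 0:
        hit = np.nonzero(rng.random(arr.size) < sub_rate)[0]
        if hit.size:
            # replace with a uniformly chosen *different* base
            codes = np.searchsorted(_BASES, arr[hit])
            arr[hit] = _BASES[(codes + rng.integers(1, 4, size=hit.size)) % 4]
    if n_rate > 0:
        hit = rng.random(arr.size) < n_rate
        arr[hit] = ord("N")
    return arr.tobytes().decode("ascii")


def simulate_fixture(
    params: FixtureParams | None = None, seed: int = 0
) -> SyntheticFixture:
    """Generate taxonomy + genomes + error-bearing reads with truth labels."""
    params = params or FixtureParams()
    params.validate()
    rng = np.random.default_rng(seed)
    phylum_rank, leaf_rank = params.rank_names

    nodes = [TaxonNode(1, 1, "root", "root")]
    leaves: list[int] = []
    for p in range(params.n_phyla):
        pid = 10 + p
        nodes.append(TaxonNode(pid, 1, phylum_rank, f"{phylum_rank}{p}"))
        for g in range(params.genera_per_phylum):
            gid = 100 + p * params.genera_per_phylum + g
            nodes.append(TaxonNode(gid, pid, leaf_rank, f"{leaf_rank}{p}_{g}"))
            leaves.append(gid)
    tree = TaxonomyTree(nodes)

    genomes = {leaf: _random_genome(rng, params.genome_length) for leaf in leaves}
    seq_taxon_map = {f"ref_{leaf}": leaf for leaf in leaves}
    sequences = {f"ref_{leaf}": genomes[leaf] for leaf in leaves}

    reads: list[Read] = []
    truth: dict[str, dict[str, int]] = {}
    leaf_arr = np.array(leaves)
    src = rng.integers(0, len(leaves), size=params.n_reads)
    pos = rng.integers(0, params.genome_length - params.read_length + 1,
                       size=params.n_reads)
    strand = rng.integers(0, 2, size=params.n_reads)
    for i in range(params.n_reads):
        leaf = int(leaf_arr[src[i]])
        frag = genomes[leaf][pos[i]: pos[i] + params.read_length]
        if strand[i]:
            frag = reverse_complement(frag)
        frag = _mutate(rng, frag, params.substitution_rate, params.n_injection_rate)
        rid = f"read_{i:06d}"
        reads.append(Read(rid, frag))
        truth[rid] = {
            rank: ancestor_at_rank(tree, leaf, rank) for rank in params.rank_names
        }
    return SyntheticFixture(
        tree, genomes, reads, truth, seq_taxon_map, sequences, params, seed
    )


def write_fixture(fixture: SyntheticFixture, out_dir) -> dict[str, Path]:
    """Materialise a fixture as plain-text files.

    Writes reference genomes and reads as FASTA (read headers carry
    ``taxid=<leaf>``), the taxonomy as nodes/names dump files, the
    sequence→taxon map, a per-rank truth table (TSV) and the
    generation parameters (JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "references": out / "references.fasta",
        "reads": out / "reads.fasta",
        "nodes": out / "nodes.dmp",
        "names": out / "names.dmp",
        "seq2tax": out / "seq2tax.tsv",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    with open(paths["references"], "w") as fh:
        for sid in sorted(fixture.sequences):
            fh.write(f">{sid}\n{fixture.sequences[sid]}\n")
    leaf_rank = fixture.params.rank_names[-1]
    with open(paths["reads"], "w") as fh:
        for read in fixture.reads:
            fh.write(
                f">{read.read_id} taxid={fixture.truth[read.read_id][leaf_rank]}\n"
                f"{read.sequence}\n"
            )
    with open(paths["nodes"], "w") as fh:
        for node in sorted(fixture.tree.nodes.values(), key=lambda n: n.taxon_id):
            fh.write(f"{node.taxon_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|\n")
    with open(paths["names"], "w") as fh:
        for node in sorted(fixture.tree.nodes.values(), key=lambda n: n.taxon_id):
            fh.write(f"{node.taxon_id}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")
    with open(paths["seq2tax"], "w") as fh:
        for sid in sorted(fixture.seq_taxon_map):
            fh.write(f"{sid}\t{fixture.seq_taxon_map[sid]}\n")
    with open(paths["truth"], "w") as fh:
        ranks = list(fixture.params.rank_names)
        fh.write("read_id\t" + "\t".join(ranks) + "\n")
        for read in fixture.reads:
            row = "\t".join(str(fixture.truth[read.read_id][r]) for r in ranks)
            fh.write(f"{read.read_id}\t{row}\n")
    with open(paths["params"], "w") as fh:
        payload = asdict(fixture.params)
        payload["rank_names"] = list(payload["rank_names"])
        payload["seed"] = fixture.seed
        json.dump(payload, fh, indent=2)
    return paths


def filter_ambiguous_reads(
    reads: Sequence[Read], max_unknown_fraction: float = 0.5
) -> list[Read]:
    """Drop reads whose non-ACGT fraction exceeds the threshold.

    With the default 0.5 this is the "reduced dataset" rule: reads
    containing more than 50% unknown nucleotides are removed.
    """
    kept = []
    for read in reads:
        n = len(read.sequence)
        unknown = sum(1 for b in read.sequence.upper() if b not in "ACGT")
        if n == 0 or unknown / n <= max_unknown_fraction:
            kept.append(read)
    return kept
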