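"""Iterative top-down classification along the taxonomy tree.

Classification proceeds rank by rank down a configured rank path
(default phylum → class → order → family → genus). At the first rank
every read is compared against every group; at each deeper rank a read
is compared only against the subgroups of the group it was assigned to
one level up — the branch's previous-level output file is exactly the
next level's input. NC reads stop descending; a winning group with no
subgroups at the next rank terminates its branch, and the read's final
label is that deepest assignment.

Under the multi-assignment ("all") tie policy a read tied across
several parents descends each parent's branch independently; the
provenance chain recorded per branch keeps the descents apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .assignment import AssignmentConfig, TIE_POLICIES, assign_read_set
from .database import KmerDatabase, build_database
from .scoring import Read, compare_read_set
from .taxonomy import Group, TaxonomyTree, group_sequences_by_rank, subgroups

__all__ = [
    "DEFAULT_RANK_PATH",
    "RunConfig",
    "RankLevelResult",
    "classify_at_rank",
    "classify_tree",
    "final_labels",
]

DEFAULT_RANK_PATH = ("phylum", "class", "order", "family", "genus")


@dataclass
class RunConfig:
    """Parameters of a full tree-descent run."""

    k: int
    mc: float = 30.0
    kprime: int = 1
    tie_policy: str = "all"
    use_mismatch: bool = True
    rank_path: Sequence[str] = DEFAULT_RANK_PATH
    seed: int | None = None
    special_groups: Sequence[int] = ()
    mc_by_rank: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie policy {self.tie_policy!r} not one of {TIE_POLICIES}")
        if not self.rank_path:
            raise ValueError("rank path must name at least one rank")

    def mc_at(self, rank: str) -> float:
        return self.mc_by_rank.get(rank, self.mc)


@dataclass
class RankLevelResult:
    """Outcome of one rank: per-group read-id sets, NC set, provenance."""

    rank: str
    assigned: dict[str, set[str]] = field(default_factory=dict)
    nc: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)
    groups: dict[str, Group] = field(default_factory=dict)


def classify_at_rank(
    reads: Sequence[Read],
    groups_with_dbs: Sequence[tuple[Group, KmerDatabase | None]],
    config: RunConfig,
    rank: str | None = None,
) -> RankLevelResult:
    """Compare + assign all reads against the given groups at one rank."""
    rank = rank or (groups_with_dbs[0][0].rank if groups_with_dbs else config.rank_path[0])
    for grp, db in groups_with_dbs:
        if db is None:
            raise ValueError(f"group {grp.group_id} has no database built")
        if db.k != config.k:
            raise ValueError(
                f"group {grp.group_id}: database k={db.k} != configured k={config.k}"
            )
    result = RankLevelResult(rank=rank)
    result.groups = {grp.group_id: grp for grp, _ in groups_with_dbs}
    if not groups_with_dbs:
        result.nc = {r.read_id for r in reads}
        return result
    records = compare_read_set(
        reads, [db for _, db in groups_with_dbs], config.mc_at(rank), config.kprime
    )
    acfg = AssignmentConfig(
        k=config.k,
        mc=config.mc_at(rank),
        tie_policy=config.tie_policy,
        use_mismatch=config.use_mismatch,
        seed=config.seed,
    )
    for rec in assign_read_set(records, acfg):
        if rec.is_nc:
            result.nc.add(rec.read_id)
        for gid in rec.assigned_group_ids:
            result.assigned.setdefault(gid, set()).add(rec.read_id)
    return result


def classify_tree(
    reads: Sequence[Read],
    tree: TaxonomyTree,
    seq_taxon_map: Mapping[str, int],
    sequences: Mapping[str, str],
    config: RunConfig,
) -> list[RankLevelResult]:
    """Run the full descent: one RankLevelResult per rank on the path.

    ``sequences`` maps reference-sequence id → nucleotide string;
    group databases are built per branch as the descent reaches them.
    The input of a level-(j+1) branch is exactly the read set assigned
    to the branch's parent group at level j.
    """
    read_by_id = {r.read_id: r for r in reads}
    top_rank = config.rank_path[0]
    top_groups, _ = group_sequences_by_rank(
        tree, seq_taxon_map, top_rank, config.special_groups
    )
    if not top_groups:
        raise ValueError(f"no reference groups at rank {top_rank!r}")

    def db_for(grp: Group) -> KmerDatabase:
        seqs = [sequences[sid] for sid in sorted(grp.sequence_ids)]
        return build_database(seqs, config.k, grp.group_id)

    results: list[RankLevelResult] = []
    # (parent chain, parent group, reads to classify against its subgroups)
    level = classify_at_rank(
        reads, [(g, db_for(g)) for g in top_groups], config, top_rank
    )
    level.provenance = {gid: () for gid in level.groups}
    results.append(level)

    branches: list[tuple[tuple[str, ...], Group, list[Read]]] = [
        ((gid,), level.groups[gid], [read_by_id[rid] for rid in sorted(ids)])
        for gid, ids in sorted(level.assigned.items())
        if ids
    ]
    for rank in config.rank_path[1:]:
        level_result = RankLevelResult(rank=rank)
        next_branches: list[tuple[tuple[str, ...], Group, list[Read]]] = []
        for chain, parent, branch_reads in branches:
            children = subgroups(tree, parent, rank, seq_taxon_map)
            if not children:
                continue  # branch terminates; deepest label is the parent
            branch_result = classify_at_rank(
                branch_reads, [(g, db_for(g)) for g in children], config, rank
            )
            for gid, ids in branch_result.assigned.items():
                level_result.assigned.setdefault(gid, set()).update(ids)
                level_result.provenance[gid] = chain
                level_result.groups[gid] = branch_result.groups[gid]
                next_branches.append(
                    (
                        chain + (gid,),
                        branch_result.groups[gid],
                        [read_by_id[rid] for rid in sorted(ids)],
                    )
                )
            level_result.nc.update(branch_result.nc)
        results.append(level_result)
        branches = next_branches
    return results


def final_labels(results: Sequence[RankLevelResult]) -> dict[str, tuple[str, str]]:
    """Deepest assignment per read: read id → (rank, group id).

    With multi-assignment a read may hold several labels at its
    deepest rank; the lexicographically smallest group id is reported
    here (the full sets remain in the per-level results).
    """
    labels: dict[str, tuple[str, str]] = {}
    for level in results:
        for gid in sorted(level.assigned):
            for rid in level.assigned[gid]:
                if rid not in labels or labels[rid][0] != level.rank:
                    labels[rid] = (level.rank, gid)
    return labels
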