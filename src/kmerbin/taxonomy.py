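"""Taxonomy tree, sequence→taxon mapping, and reference-sequence groups.

Reference sequences are partitioned into groups — one group per taxon
at a chosen rank — by resolving each sequence's taxon through the tree
to its ancestor at that rank. The tree and mapping formats follow the
NCBI dump dialect: pipe-delimited ``nodes.dmp`` / ``names.dmp`` records
and a two-column sequence-id → taxon-id text file (the shape of
``gi_taxid_nucl.dmp``), read in a streaming fashion.

Selected subtrees (e.g. Viruses, Viroids) can be declared *special
groups*: their sequences form their own group regardless of rank.
Sequences whose lineage lacks the requested rank are reported as
ungrouped, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "Group",
    "load_taxonomy",
    "load_seq_taxon_map",
    "ancestor_at_rank",
    "group_sequences_by_rank",
    "subgroups",
]


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted taxonomy: nodes with parent links and rank labels.

    The root is self-parented. Construction verifies that every parent
    exists and that every node reaches the root (no cycles, no
    orphans).
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {n.taxon_id: n for n in nodes}
        if not self.nodes:
            raise ValueError("taxonomy has no nodes")
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        missing = sorted(
            n.taxon_id
            for n in self.nodes.values()
            if n.parent_id not in self.nodes
        )
        if missing:
            raise ValueError(f"nodes with absent parents: {missing}")
        for tid in self.nodes:
            seen = set()
            cur = tid
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy through node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, taxon_id: int) -> list[int]:
        """Root-to-self chain of taxon ids."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id}")
        chain = [taxon_id]
        while chain[-1] != self.root:
            chain.append(self.nodes[chain[-1]].parent_id)
        return chain[::-1]

    def is_descendant(self, taxon_id: int, ancestor_id: int) -> bool:
        """True iff ``ancestor_id`` is on ``taxon_id``'s lineage (self counts)."""
        return ancestor_id in self.lineage(taxon_id)

    def name_of(self, taxon_id: int) -> str:
        return self.nodes[taxon_id].name or str(taxon_id)


@dataclass
class Group:
    """One taxon's set of reference sequences at one rank."""

    group_id: str
    rank: str
    taxon_id: int
    sequence_ids: set[str] = field(default_factory=set)
    parent_group_id: str | None = None


def _group_id(rank: str, taxon_id: int) -> str:
    return f"{rank}_{taxon_id}"


def load_taxonomy(nodes_file, names_file=None) -> TaxonomyTree:
    """Parse pipe-delimited nodes/names dump files into a tree.

    ``nodes_file`` rows: taxon id | parent id | rank | ...; an optional
    ``names_file`` (taxon id | name | unique name | name class |)
    supplies display names, of which only ``scientific name`` entries
    are used.
    """
    nodes: dict[int, tuple[int, str]] = {}
    with open(nodes_file) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("|")]
            if len(fields) < 3:
                raise ValueError(f"{nodes_file}:{lineno}: expected id|parent|rank")
            nodes[int(fields[0])] = (int(fields[1]), fields[2])
    if not nodes:
        raise ValueError(f"{nodes_file}: empty nodes file")
    names: dict[int, str] = {}
    if names_file is not None:
        with open(names_file) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = [f.strip() for f in line.split("|")]
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
    return TaxonomyTree(
        TaxonNode(tid, parent, rank, names.get(tid, ""))
        for tid, (parent, rank) in nodes.items()
    )


def load_seq_taxon_map(path) -> dict[str, int]:
    """Stream a two-column sequence-id → taxon-id text file into a dict.

    Duplicate sequence ids are tolerated only when they agree on the
    taxon; a conflicting duplicate or a malformed line is an error
    carrying the line number.
    """
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'sequence-id taxon-id', got {line!r}"
                )
            seq_id, raw_tax = parts
            try:
                taxon = int(raw_tax)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: taxon id {raw_tax!r} is not an integer"
                ) from None
            if seq_id in mapping and mapping[seq_id] != taxon:
                raise ValueError(
                    f"{path}:{lineno}: sequence {seq_id} mapped to both "
                    f"{mapping[seq_id]} and {taxon}"
                )
            mapping[seq_id] = taxon
    return mapping


def ancestor_at_rank(tree: TaxonomyTree, taxon_id: int, rank: str) -> int | None:
    """The unique ancestor (or self) of ``taxon_id`` labelled ``rank``, else None."""
    for tid in tree.lineage(taxon_id):
        if tree.nodes[tid].rank == rank:
            return tid
    return None


def group_sequences_by_rank(
    tree: TaxonomyTree,
    seq_taxon_map: Mapping[str, int],
    rank: str,
    special_groups: Iterable[int] = (),
) -> tuple[list[Group], list[str]]:
    """Partition sequences into one group per rank-level taxon.

    A sequence under any ``special_groups`` subtree root joins that
    root's own group regardless of rank. Returns the groups (sorted by
    taxon id, special groups last) and the list of ungrouped sequence
    ids: sequences with an unknown taxon or a lineage lacking the
    rank.
    """
    special = list(special_groups)
    by_taxon: dict[int, Group] = {}
    special_by_taxon: dict[int, Group] = {}
    ungrouped: list[str] = []
    for seq_id in sorted(seq_taxon_map):
        taxon = seq_taxon_map[seq_id]
        if taxon not in tree:
            ungrouped.append(seq_id)
            continue
        lineage = tree.lineage(taxon)
        special_hit = next((s for s in special if s in lineage), None)
        if special_hit is not None:
            grp = special_by_taxon.setdefault(
                special_hit,
                Group(_group_id("special", special_hit), "special", special_hit),
            )
            grp.sequence_ids.add(seq_id)
            continue
        anc = ancestor_at_rank(tree, taxon, rank)
        if anc is None:
            ungrouped.append(seq_id)
            continue
        grp = by_taxon.setdefault(anc, Group(_group_id(rank, anc), rank, anc))
        grp.sequence_ids.add(seq_id)
    groups = [by_taxon[t] for t in sorted(by_taxon)]
    groups += [special_by_taxon[t] for t in sorted(special_by_taxon)]
    return groups, ungrouped


def subgroups(
    tree: TaxonomyTree,
    parent: Group,
    child_rank: str,
    seq_taxon_map: Mapping[str, int],
) -> list[Group]:
    """Split a parent group's sequences by their ``child_rank`` ancestor.

    The result is a possibly partial partition of the parent's
    sequences (sequences whose lineage lacks the child rank are left
    out); each child group records the parent's id. Querying a rank
    that sits above the parent in the tree is an error.
    """
    by_taxon: dict[int, Group] = {}
    for seq_id in sorted(parent.sequence_ids):
        taxon = seq_taxon_map[seq_id]
        anc = ancestor_at_rank(tree, taxon, child_rank)
        if anc is None:
            continue
        if anc != parent.taxon_id and tree.is_descendant(parent.taxon_id, anc):
            raise ValueError(
                f"rank {child_rank!r} lies above the parent group "
                f"{parent.group_id} in the taxonomy"
            )
        grp = by_taxon.setdefault(
            anc,
            Group(
                _group_id(child_rank, anc),
                child_rank,
                anc,
                parent_group_id=parent.group_id,
            ),
        )
        grp.sequence_ids.add(seq_id)
    return [by_taxon[t] for t in sorted(by_taxon)]
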