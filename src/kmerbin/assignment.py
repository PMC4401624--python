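"""Assignment of reads to their best-matching group(s).

Per read, the candidate pool is the set of groups whose record has
*match* status (Ξ >= MC). When that pool is empty and mismatch records
are admitted, the best *mismatch* group can still win provided its
score contains at least one whole k-mer (ξ >= k). The winner is the
argmax over ξ; equal top scores are resolved by the tie policy:

* ``all``    — assign to every tied group (multi-assignment);
* ``first``  — the lexicographically smallest group id (the
  deterministic reading of "any group");
* ``random`` — one tied group drawn with a seeded generator;
* ``none``   — a tie disqualifies the read (it becomes NC), the
  counting convention used when multi-assignments must not inflate
  per-group tallies.

A read meeting no criterion is NC (not classified).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scoring import MATCH, MISMATCH, MatchResult

__all__ = [
    "TIE_POLICIES",
    "AssignmentConfig",
    "AssignmentRecord",
    "assign_read",
    "assign_read_set",
    "partition_outputs",
]

TIE_POLICIES = ("all", "first", "random", "none")
NC_FILENAME = "not_classified.fasta"


@dataclass
class AssignmentConfig:
    k: int
    mc: float = 30.0
    tie_policy: str = "all"
    use_mismatch: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(
                f"tie policy {self.tie_policy!r} not one of {TIE_POLICIES}"
            )


@dataclass
class AssignmentRecord:
    """A read's final label(s) at one rank; empty group list = NC."""

    read_id: str
    assigned_group_ids: list[str] = field(default_factory=list)
    winning_xi: int = 0
    winning_Xi: float = 0.0
    via_mismatch: bool = False

    @property
    def is_nc(self) -> bool:
        return not self.assigned_group_ids


def assign_read(
    records: Sequence[MatchResult],
    config: AssignmentConfig,
    rng: np.random.Generator | None = None,
) -> AssignmentRecord:
    """Pick the best group(s) for one read from its per-group records."""
    if not records:
        raise ValueError("no records for read")
    read_ids = {r.read_id for r in records}
    if len(read_ids) != 1:
        raise ValueError(f"records mix several reads: {sorted(read_ids)}")
    read_id = records[0].read_id
    candidates = [r for r in records if r.status == MATCH]
    via_mismatch = False
    if not candidates and config.use_mismatch:
        candidates = [
            r for r in records if r.status == MISMATCH and r.xi >= config.k
        ]
        via_mismatch = bool(candidates)
    if not candidates:
        return AssignmentRecord(read_id)
    best_xi = max(r.xi for r in candidates)
    winners = sorted(r.group_id for r in candidates if r.xi == best_xi)
    if len(winners) > 1:
        if config.tie_policy == "first":
            winners = winners[:1]
        elif config.tie_policy == "random":
            if rng is None:
                rng = np.random.default_rng(config.seed)
            winners = [winners[int(rng.integers(len(winners)))]]
        elif config.tie_policy == "none":
            return AssignmentRecord(read_id)
    best = next(r for r in candidates if r.xi == best_xi)
    return AssignmentRecord(read_id, winners, best_xi, best.Xi, via_mismatch)


def assign_read_set(
    records_by_group: Mapping[str, Sequence[MatchResult]],
    config: AssignmentConfig,
) -> list[AssignmentRecord]:
    """Assign every read appearing in the per-group record streams.

    Records are regrouped per read; each read must have a record for
    every compared group. One generator, seeded from the config, serves
    all random tie-breaks so runs are reproducible.
    """
    per_read: dict[str, list[MatchResult]] = {}
    order: list[str] = []
    for group_records in records_by_group.values():
        for rec in group_records:
            if rec.read_id not in per_read:
                per_read[rec.read_id] = []
                order.append(rec.read_id)
            per_read[rec.read_id].append(rec)
    n_groups = len(records_by_group)
    rng = np.random.default_rng(config.seed)
    out = []
    for read_id in order:
        recs = per_read[read_id]
        if len(recs) != n_groups:
            raise ValueError(
                f"read {read_id} has {len(recs)} records for {n_groups} groups"
            )
        out.append(assign_read(recs, config, rng))
    return out


def partition_outputs(
    assignments: Iterable[AssignmentRecord],
    reads: Mapping[str, str],
    out_dir,
    config: AssignmentConfig | None = None,
) -> dict:
    """Write one FASTA per group that received reads, plus the NC file.

    ``reads`` maps read id → nucleotide sequence (the scoring stage's
    intermediary records carry no sequences; they are re-attached
    here). Group FASTA headers carry ``|group=<id>|xi=<int>|Xi=<1dp>``.
    Only groups with at least one read get a file. Returns the summary
    (also written as ``summary.json``): per-group counts, NC count and
    the config echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments = list(assignments)
    for rec in assignments:
        if rec.read_id not in reads:
            raise ValueError(f"assigned read {rec.read_id!r} absent from read source")
    per_group: dict[str, list[AssignmentRecord]] = {}
    nc: list[AssignmentRecord] = []
    for rec in assignments:
        if rec.is_nc:
            nc.append(rec)
        for gid in rec.assigned_group_ids:
            per_group.setdefault(gid, []).append(rec)
    for gid, recs in sorted(per_group.items()):
        with open(out_dir / f"{gid}.fasta", "w") as fh:
            for rec in recs:
                fh.write(
                    f">{rec.read_id}|group={gid}|xi={rec.winning_xi}"
                    f"|Xi={rec.winning_Xi:.1f}\n{reads[rec.read_id]}\n"
                )
    with open(out_dir / NC_FILENAME, "w") as fh:
        for rec in nc:
            fh.write(f">{rec.read_id}\n{reads[rec.read_id]}\n")
    summary = {
        "groups": {gid: len(recs) for gid, recs in sorted(per_group.items())},
        "not_classified": len(nc),
        "total_reads": len(assignments),
        "config": (
            {
                "k": config.k,
                "mc": config.mc,
                "tie_policy": config.tie_policy,
                "use_mismatch": config.use_mismatch,
                "seed": config.seed,
            }
            if config is not None
            else None
        ),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
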