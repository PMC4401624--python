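"""Evaluation metrics for labelled read sets.

Over a read set with known origin, with TP and FP the numbers of
correctly and incorrectly classified reads:

* Classified   = 100 · (TP + FP) / total
* Sensitivity  = 100 · TP / total
* Precision    = 100 · TP / (TP + FP)   (undefined when nothing is
  classified, reported as ``None``)

Two counting modes exist. In ``single`` mode every read holds at most
one label and TP + FP + NC = total. In ``multi`` mode a read assigned
to several tied groups contributes each of its assignments separately,
so TP + FP may exceed the read count. A read with no assignment at the
evaluated rank is NC — in particular a read whose descent stopped at a
higher rank counts as unclassified here, never as correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .assignment import AssignmentRecord

__all__ = ["MetricsReport", "evaluate"]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    nc: int
    total: int
    counting_mode: str = "single"

    def __post_init__(self) -> None:
        if self.counting_mode == "single" and self.tp + self.fp + self.nc != self.total:
            raise ValueError("single-mode counts must satisfy TP + FP + NC = total")

    @property
    def classified_percent(self) -> float:
        return 100.0 * (self.tp + self.fp) / self.total if self.total else 0.0

    @property
    def sensitivity_percent(self) -> float:
        return 100.0 * self.tp / self.total if self.total else 0.0

    @property
    def precision_percent(self) -> float | None:
        classified = self.tp + self.fp
        return 100.0 * self.tp / classified if classified else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "nc": self.nc,
            "total": self.total,
            "counting_mode": self.counting_mode,
            "classified_percent": self.classified_percent,
            "sensitivity_percent": self.sensitivity_percent,
            "precision_percent": self.precision_percent,
        }


def evaluate(
    assignments: Iterable[AssignmentRecord],
    truth: Mapping[str, str],
    counting_mode: str = "single",
) -> MetricsReport:
    """Score assignments against truth expressed as group ids.

    ``truth`` maps every read id to its correct group id at the
    evaluated rank; reads present in the truth table but absent from
    the assignments (or assigned nothing) are NC. An assignment for an
    unknown read id is an error, as is a multi-assigned record in
    ``single`` mode (use ``multi``, or the ``none`` tie policy
    upstream).
    """
    if counting_mode not in ("single", "multi"):
        raise ValueError(f"counting mode {counting_mode!r} not 'single' or 'multi'")
    tp = fp = 0
    seen: set[str] = set()
    classified_reads = 0
    for rec in assignments:
        if rec.read_id not in truth:
            raise ValueError(f"assignment for unknown read {rec.read_id!r}")
        if rec.read_id in seen:
            raise ValueError(f"duplicate assignment record for {rec.read_id!r}")
        seen.add(rec.read_id)
        if rec.is_nc:
            continue
        classified_reads += 1
        if counting_mode == "single":
            if len(rec.assigned_group_ids) > 1:
                raise ValueError(
                    f"read {rec.read_id!r} is multi-assigned; use counting_mode='multi'"
                )
            if rec.assigned_group_ids[0] == truth[rec.read_id]:
                tp += 1
            else:
                fp += 1
        else:
            for gid in rec.assigned_group_ids:
                if gid == truth[rec.read_id]:
                    tp += 1
                else:
                    fp += 1
    total = len(truth)
    nc = total - classified_reads
    return MetricsReport(tp, fp, nc, total, counting_mode)
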