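"""Chronological grouping of a cohort by CAS registration order.

Records are sorted by CAS key (major, minor) and partitioned into fixed-size
groups; the tail remainder that cannot fill a complete group is dropped, not
kept as a short group.  Per-group arithmetic means of per-molecule values are
the basic unit of every downstream trend analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chem_io import CasKey, CompoundRecord, Cohort, parse_cas, sort_records

logger = logging.getLogger(__name__)


@dataclass
class Group:
    index: int  # 1-based
    members: list[str]  # record_ids, CAS order
    cas_min: CasKey
    cas_max: CasKey


@dataclass
class GroupedCohort:
    cohort: Cohort
    group_size: int
    groups: list[Group] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_grouped(self) -> int:
        return sum(len(g.members) for g in self.groups)

    def member_ids(self) -> list[str]:
        return [rid for g in self.groups for rid in g.members]

    def group_of(self) -> dict[str, int]:
        return {rid: g.index for g in self.groups for rid in g.members}


def sort_and_group(
    records: Sequence[CompoundRecord], group_size: int = 5000
) -> GroupedCohort:
    """Sort by CAS key and cut into complete groups of ``group_size``.

    ``floor(n / group_size)`` groups are produced; the last ``n mod group_size``
    records are dropped and listed.  Fewer records than one group is a warning,
    not an error.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    cohorts = {r.cohort for r in records}
    if len(cohorts) > 1:
        raise ValueError(f"records span multiple cohorts: {sorted(c.value for c in cohorts)}")
    cohort = cohorts.pop() if cohorts else Cohort.NP
    ordered = sort_records(records)
    n_groups = len(ordered) // group_size
    if n_groups == 0 and ordered:
        logger.warning(
            "only %d records for group size %d: zero groups", len(ordered), group_size
        )
    grouped = GroupedCohort(cohort=cohort, group_size=group_size)
    for gi in range(n_groups):
        chunk = ordered[gi * group_size : (gi + 1) * group_size]
        grouped.groups.append(
            Group(
                index=gi + 1,
                members=[r.record_id for r in chunk],
                cas_min=parse_cas(chunk[0].cas),
                cas_max=parse_cas(chunk[-1].cas),
            )
        )
    grouped.dropped = [r.record_id for r in ordered[n_groups * group_size :]]
    return grouped


def group_means(
    grouped: GroupedCohort, per_molecule_values: Mapping[str, float | None]
) -> pd.DataFrame:
    """Per-group arithmetic mean over non-missing member values.

    Missing = absent key, None, or NaN; a group whose members are all missing
    gets mean NaN and is flagged by its missing count.  Columns:
    ``group_index, mean, n, n_missing``.
    """
    rows = []
    for g in grouped.groups:
        vals = []
        n_missing = 0
        for rid in g.members:
            v = per_molecule_values.get(rid)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                n_missing += 1
            else:
                vals.append(float(v))
        rows.append(
            {
                "group_index": g.index,
                "mean": sum(vals) / len(vals) if vals else float("nan"),
                "n": len(vals),
                "n_missing": n_missing,
            }
        )
    return pd.DataFrame(rows, columns=["group_index", "mean", "n", "n_missing"])
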