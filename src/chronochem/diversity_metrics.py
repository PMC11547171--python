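"""Per-group fragment diversity statistics and ring-assembly first-occurrence
catalog.

For each chronological group of M molecules and one fragment type, three
ratios summarize structural diversity:

* abundance   = N / M        (N: fragment occurrences in the group)
* uniqueness  = N_sing / M   (N_sing: singleton types — occurring exactly once
  in the whole cohort — present in the group)
* novelty     = N_novel / M  (N_novel: distinct types first seen in this group,
  in chronological group order)

N counts occurrences (instances); N_sing and N_novel count distinct types.
Singleton status is decided within the fragment's own cohort over the grouped
molecules only (the dropped tail does not participate); a flag switches to a
joint NP+SC singleton universe.

Glycosylation statistics: per-group fraction of glycosides and mean sugar
rings per glycoside.  The ring-assembly catalog tallies per-cohort frequencies
and earliest CAS keys, assigning each assembly to one of four categories:
unique to one cohort, or common with the earlier first registration deciding
NP-first vs SC-first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_io import CasKey
from .cohort import GroupedCohort
from .deglyco import DeglycosylationResult
from .fragments import FragmentSet


class FragmentType(str, Enum):
    scaffold = "scaffold"
    ring_assembly = "ring_assembly"
    side_chain = "side_chain"
    recap = "recap"


@dataclass
class FragmentGroupStats:
    group_index: int
    fragment_type: FragmentType
    N: int
    M: int
    N_sing: int
    N_novel: int

    @property
    def abundance(self) -> float:
        return self.N / self.M

    @property
    def uniqueness(self) -> float:
        return self.N_sing / self.M

    @property
    def novelty(self) -> float:
        return self.N_novel / self.M


@dataclass
class GlycoGroupStats:
    group_index: int
    glycosylation_ratio: float
    mean_sugar_rings_per_glycoside: float | None


class AssemblyCategory(str, Enum):
    NP_unique = "NP_unique"
    SC_unique = "SC_unique"
    common_NP_first = "common_NP_first"
    common_SC_first = "common_SC_first"


@dataclass
class CatalogEntry:
    assembly: str
    freq_NP: int
    freq_SC: int
    first_cas_NP: CasKey | None
    first_cas_SC: CasKey | None
    category: AssemblyCategory


@dataclass
class RingAssemblyCatalog:
    entries: list[CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assembly": e.assembly,
                "freq_NP": e.freq_NP,
                "freq_SC": e.freq_SC,
                "first_cas_NP": f"{e.first_cas_NP.major}-{e.first_cas_NP.minor:02d}"
                if e.first_cas_NP
                else "",
                "first_cas_SC": f"{e.first_cas_SC.major}-{e.first_cas_SC.minor:02d}"
                if e.first_cas_SC
                else "",
                "category": e.category.value,
            }
            for e in self.entries
        )


def _fragment_multiset(fs: FragmentSet, fragment_type: FragmentType) -> Counter:
    if fragment_type is FragmentType.scaffold:
        return Counter({fs.scaffold: 1}) if fs.scaffold is not None else Counter()
    if fragment_type is FragmentType.ring_assembly:
        return fs.ring_assemblies
    if fragment_type is FragmentType.side_chain:
        return fs.side_chains
    return fs.recap_fragments


def fragment_group_stats(
    grouped: GroupedCohort,
    fragsets: Mapping[str, FragmentSet],
    fragment_type: FragmentType,
    extra_universe: Iterable[Counter] = (),
) -> list[FragmentGroupStats]:
    """Abundance/uniqueness/novelty rows, one per chronological group.

    ``extra_universe`` extends the singleton-determination universe with
    fragment multisets from outside this cohort (the joint-universe variant);
    by default singletons are per-cohort.
    """
    per_group: list[list[Counter]] = []
    cohort_counts: Counter = Counter()
    for g in grouped.groups:
        multisets = [_fragment_multiset(fragsets[rid], fragment_type) for rid in g.members]
        per_group.append(multisets)
        for ms in multisets:
            cohort_counts.update(ms)
    universe_counts = Counter(cohort_counts)
    for ms in extra_universe:
        universe_counts.update(ms)
    singles = {t for t, c in universe_counts.items() if c == 1 and cohort_counts[t] >= 1}

    seen: set = set()
    out: list[FragmentGroupStats] = []
    for g, multisets in zip(grouped.groups, per_group):
        group_counts: Counter = Counter()
        for ms in multisets:
            group_counts.update(ms)
        novel = set(group_counts) - seen
        seen.update(group_counts)
        out.append(
            FragmentGroupStats(
                group_index=g.index,
                fragment_type=fragment_type,
                N=sum(group_counts.values()),
                M=len(g.members),
                N_sing=len(singles & set(group_counts)),
                N_novel=len(novel),
            )
        )
    return out


def stats_frame(stats: Sequence[FragmentGroupStats], cohort: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cohort": cohort,
            "fragment_type": s.fragment_type.value,
            "group_index": s.group_index,
            "N": s.N,
            "M": s.M,
            "N_sing": s.N_sing,
            "N_novel": s.N_novel,
            "abundance": s.abundance,
            "uniqueness": s.uniqueness,
            "novelty": s.novelty,
        }
        for s in stats
    )


def glyco_group_stats(
    grouped: GroupedCohort, deglyco_results: Mapping[str, DeglycosylationResult]
) -> list[GlycoGroupStats]:
    """A glycoside is any molecule with >=1 sugar ring removed; the per-group
    mean of removed rings is taken over glycosides only."""
    out = []
    for g in grouped.groups:
        removals = [deglyco_results[rid].n_sugar_rings_removed for rid in g.members]
        glyco = [n for n in removals if n >= 1]
        out.append(
            GlycoGroupStats(
                group_index=g.index,
                glycosylation_ratio=len(glyco) / len(g.members),
                mean_sugar_rings_per_glycoside=sum(glyco) / len(glyco) if glyco else None,
            )
        )
    return out


def build_ring_assembly_catalog(
    np_items: Sequence[tuple[Counter, CasKey]],
    sc_items: Sequence[tuple[Counter, CasKey]],
    min_freq: int = 5,
) -> RingAssemblyCatalog:
    """Catalog of ring assemblies surviving the per-cohort frequency filter.

    ``np_items``/``sc_items``: one (assembly multiset, CAS key) pair per
    analyzed molecule.  An assembly survives if its occurrence frequency in at
    least one cohort is strictly greater than ``min_freq``; surviving entries
    keep both raw frequencies.  ``first_cas`` is the minimum CAS key among the
    cohort's carrier molecules.
    """
    freq: dict[str, Counter] = {"NP": Counter(), "SC": Counter()}
    first: dict[str, dict[str, CasKey]] = {"NP": {}, "SC": {}}
    for label, items in (("NP", np_items), ("SC", sc_items)):
        for multiset, cas in items:
            for assembly, count in multiset.items():
                freq[label][assembly] += count
                prev = first[label].get(assembly)
                if prev is None or cas < prev:
                    first[label][assembly] = cas
    survivors = {a for a in freq["NP"] if freq["NP"][a] > min_freq} | {
        a for a in freq["SC"] if freq["SC"][a] > min_freq
    }
    entries = []
    for assembly in sorted(survivors):
        f_np, f_sc = freq["NP"][assembly], freq["SC"][assembly]
        if f_np > 0 and f_sc == 0:
            cat = AssemblyCategory.NP_unique
        elif f_sc > 0 and f_np == 0:
            cat = AssemblyCategory.SC_unique
        elif first["NP"][assembly] <= first["SC"][assembly]:
            cat = AssemblyCategory.common_NP_first
        else:
            cat = AssemblyCategory.common_SC_first
        entries.append(
            CatalogEntry(
                assembly=assembly,
                freq_NP=f_np,
                freq_SC=f_sc,
                first_cas_NP=first["NP"].get(assembly),
                first_cas_SC=first["SC"].get(assembly),
                category=cat,
            )
        )
    return RingAssemblyCatalog(entries)
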