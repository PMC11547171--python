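"""Fragment abundance/uniqueness/novelty, glycosylation stats, assembly catalog."""

from collections import Counter

import pytest

from chronochem.chem_io import CompoundRecord, Cohort, cas_check_digit, parse_cas
from chronochem.cohort import sort_and_group
from chronochem.deglyco import DeglycosylationResult
from chronochem.diversity_metrics import (
    AssemblyCategory,
    FragmentType,
    build_ring_assembly_catalog,
    fragment_group_stats,
    glyco_group_stats,
)
from chronochem.fragments import FragmentSet


def cas(i):
    major, minor = 100 + i // 100, i % 100
    return f"{major}-{minor:02d}-{cas_check_digit(major, minor)}"


def records(n):
    return [
        CompoundRecord("C1CCCCC1", cas(i), Cohort.NP, f"r{i}") for i in range(n)
    ]


def fragset(rid, scaffold=None, assemblies=(), chains=(), recap=()):
    return FragmentSet(
        record_id=rid,
        scaffold=scaffold,
        ring_assemblies=Counter(assemblies),
        side_chains=Counter(chains),
        recap_fragments=Counter(recap),
    )


class TestFragmentGroupStats:
    def test_single_group_arithmetic(self):
        # scaffolds [A, A, B, none]: N=3, abundance .75; singles {B}: Nsing=1,
        # uniqueness .25; Nnovel=2, novelty .5
        grouped = sort_and_group(records(4), group_size=4)
        fragsets = {
            "r0": fragset("r0", scaffold="A"),
            "r1": fragset("r1", scaffold="A"),
            "r2": fragset("r2", scaffold="B"),
            "r3": fragset("r3", scaffold=None),
        }
        (s,) = fragment_group_stats(grouped, fragsets, FragmentType.scaffold)
        assert (s.N, s.M, s.N_sing, s.N_novel) == (3, 4, 1, 2)
        assert (s.abundance, s.uniqueness, s.novelty) == (0.75, 0.25, 0.5)

    def test_two_groups_novelty(self):
        grouped = sort_and_group(records(4), group_size=2)
        fragsets = {
            "r0": fragset("r0", scaffold="A"),
            "r1": fragset("r1", scaffold="A"),
            "r2": fragset("r2", scaffold="A"),
            "r3": fragset("r3", scaffold="B"),
        }
        g1, g2 = fragment_group_stats(grouped, fragsets, FragmentType.scaffold)
        assert g1.novelty == 0.5  # A new
        assert g2.N_novel == 1 and g2.novelty == 0.5  # B new

    def test_all_acyclic_is_zero(self):
        grouped = sort_and_group(records(3), group_size=3)
        fragsets = {f"r{i}": fragset(f"r{i}") for i in range(3)}
        (s,) = fragment_group_stats(grouped, fragsets, FragmentType.scaffold)
        assert s.N == 0 and s.abundance == 0 and s.uniqueness == 0 and s.novelty == 0

    def test_first_group_everything_is_novel(self):
        grouped = sort_and_group(records(3), group_size=3)
        fragsets = {
            "r0": fragset("r0", recap=["x", "y"]),
            "r1": fragset("r1", recap=["x"]),
            "r2": fragset("r2", recap=["z"]),
        }
        (s,) = fragment_group_stats(grouped, fragsets, FragmentType.recap)
        assert s.N_novel == 3  # every distinct type present is novel

    def test_novelty_partitions_type_universe(self):
        grouped = sort_and_group(records(9), group_size=3)
        import random

        rng = random.Random(5)
        fragsets = {
            f"r{i}": fragset(
                f"r{i}", assemblies=[rng.choice("ABCDE") for _ in range(rng.randint(0, 3))]
            )
            for i in range(9)
        }
        stats = fragment_group_stats(grouped, fragsets, FragmentType.ring_assembly)
        distinct = {
            t
            for i in range(9)
            for t in fragsets[f"r{i}"].ring_assemblies
            if f"r{i}" in {rid for g in grouped.groups for rid in g.members}
        }
        assert sum(s.N_novel for s in stats) == len(distinct)
        total = sum(
            sum(fragsets[rid].ring_assemblies.values())
            for g in grouped.groups
            for rid in g.members
        )
        assert sum(s.N for s in stats) == total


class TestGlycoStats:
    def make(self, removals):
        grouped = sort_and_group(records(len(removals)), group_size=len(removals))
        results = {
            f"r{i}": DeglycosylationResult("C", n, False) for i, n in enumerate(removals)
        }
        return glyco_group_stats(grouped, results)[0]

    def test_mixed_group(self):
        s = self.make([0, 0, 1, 3])
        assert s.glycosylation_ratio == 0.5
        assert s.mean_sugar_rings_per_glycoside == 2.0

    def test_no_glycosides(self):
        s = self.make([0, 0, 0])
        assert s.glycosylation_ratio == 0 and s.mean_sugar_rings_per_glycoside is None

    def test_all_single_sugar(self):
        s = self.make([1, 1])
        assert s.glycosylation_ratio == 1 and s.mean_sugar_rings_per_glycoside == 1.0


class TestCatalog:
    def items(self, spec):
        # spec: list of (assembly names per molecule, cas string)
        return [(Counter(names), parse_cas(c)) for names, c in spec]

    def test_unique_categories(self):
        catalog = build_ring_assembly_catalog(
            self.items([(["A"], cas(i)) for i in range(10)]),
            [],
            min_freq=5,
        )
        (e,) = catalog.entries
        assert e.category is AssemblyCategory.NP_unique and e.freq_NP == 10

    def test_common_np_first(self):
        np_items = self.items([(["A"], "50-00-0")] + [(["A"], cas(i)) for i in range(6)])
        sc_items = self.items([(["A"], "7732-18-5")] + [(["A"], cas(i + 50)) for i in range(8)])
        (e,) = build_ring_assembly_catalog(np_items, sc_items, min_freq=5).entries
        assert e.category is AssemblyCategory.common_NP_first
        assert e.first_cas_NP.sort_key == (50, 0)

    def test_common_sc_first(self):
        np_items = self.items([(["A"], "7732-18-5")] + [(["A"], cas(i)) for i in range(6)])
        sc_items = self.items([(["A"], "50-00-0")] + [(["A"], cas(i + 50)) for i in range(6)])
        (e,) = build_ring_assembly_catalog(np_items, sc_items, min_freq=5).entries
        assert e.category is AssemblyCategory.common_SC_first

    def test_frequency_filter(self):
        np_items = self.items([(["A"], cas(i)) for i in range(3)])
        catalog = build_ring_assembly_catalog(np_items, [], min_freq=5)
        assert len(catalog) == 0

    def test_survivor_keeps_both_raw_counts(self):
        np_items = self.items([(["A"], cas(i)) for i in range(10)])
        sc_items = self.items([(["A"], cas(i + 50)) for i in range(2)])
        (e,) = build_ring_assembly_catalog(np_items, sc_items, min_freq=5).entries
        assert (e.freq_NP, e.freq_SC) == (10, 2)
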