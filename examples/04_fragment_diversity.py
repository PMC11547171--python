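"""Fragment decompositions and per-group diversity statistics.

Each molecule yields a Bemis–Murcko scaffold, ring assemblies, side chains
and RECAP fragments; per chronological group the package reports
abundance N/M, uniqueness N_sing/M and novelty N_novel/M.
"""

from rdkit import Chem

from chronochem import FragmentType, GeneratorConfig, decompose, generate_cohorts, sort_and_group
from chronochem.diversity_metrics import fragment_group_stats

mol = Chem.MolFromSmiles("CC(=O)Nc1ccc(OC2CCCCC2)cc1")
fs = decompose(mol, "demo")
print("scaffold:       ", fs.scaffold)
print("ring assemblies:", dict(fs.ring_assemblies))
print("side chains:    ", dict(fs.side_chains))
print("RECAP fragments:", dict(fs.recap_fragments))
# '*' marks an attachment point; RECAP pieces below 4 heavy atoms are dropped

cohorts = generate_cohorts(GeneratorConfig(n_per_cohort=300, group_size=50, seed=4))
grouped = sort_and_group(cohorts.np_records, group_size=50)
fragsets = {
    r.record_id: decompose(Chem.MolFromSmiles(r.structure), r.record_id)
    for r in cohorts.np_records
}
print("\ngroup  N    M   N_sing N_novel abundance uniqueness novelty  (scaffolds)")
for s in fragment_group_stats(grouped, fragsets, FragmentType.scaffold):
    print(f"{s.group_index:4d} {s.N:4d} {s.M:4d} {s.N_sing:6d} {s.N_novel:7d} "
          f"{s.abundance:9.3f} {s.uniqueness:10.3f} {s.novelty:7.3f}")
# group 1 has maximal novelty by construction: every scaffold is first seen there
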