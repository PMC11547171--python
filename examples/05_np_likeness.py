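"""Train an NP-likeness scorer and a BR similarity from synthetic corpora.

The score is the per-heavy-atom sum of log10 frequency ratios of circular
atom environments between NP-like and SC-like training sets, clipped to
[-5, 5]; the BR score is the maximum Tanimoto similarity to a reference set.
"""

from chronochem import GeneratorConfig, generate_cohorts, np_likeness_score, train_np_likeness
from chronochem.biorelevance import br_score, reference_fingerprints

cohorts = generate_cohorts(GeneratorConfig(n_per_cohort=300, group_size=50, seed=21))
table = train_np_likeness(
    [r.structure for r in cohorts.np_records],
    [r.structure for r in cohorts.sc_records],
)

probes = {
    "decalin diol (NP-like)": "OC1CCC2CCCC(O)C2C1",
    "chloro-biaryl nitrile (SC-like)": "N#Cc1ccc(-c2ccccc2Cl)cc1",
}
for name, smiles in probes.items():
    print(f"{name:34s} NP-likeness {np_likeness_score(smiles, table):+.2f}")
# positive = substructures at home among natural products, negative = synthetic

refs = reference_fingerprints(cohorts.reference_structures)
for name, smiles in probes.items():
    print(f"{name:34s} BR score    {br_score(smiles, refs):.3f}")
# BR near 1 means a close biologically-relevant neighbour exists in the
# reference set
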