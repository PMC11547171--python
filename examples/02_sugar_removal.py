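"""Detect and strip circular sugar moieties from glycosides.

A sugar ring is an isolated non-aromatic 5/6-ring with one ring oxygen and a
dense shell of exocyclic oxygens (ratio >= 0.4).  The glycosidic oxygen stays
with the aglycone.
"""

from rdkit import Chem

from chronochem import detect_circular_sugars, remove_sugars

examples = {
    "salicin (phenolic glucoside)": "OCc1ccccc1OC1OC(CO)C(O)C(O)C1O",
    "methyl glucopyranoside": "COC1OC(CO)C(O)C(O)C1O",
    "xylopyranose (pure sugar)": "OC1COC(O)C(O)C1O",
    "tetrahydropyran (not a sugar)": "C1CCOCC1",
}
for name, smiles in examples.items():
    mol = Chem.MolFromSmiles(smiles)
    rings = detect_circular_sugars(mol)
    res = remove_sugars(mol)
    print(f"{name:32s} rings detected: {len(rings)}  removed: "
          f"{res.n_sugar_rings_removed}  aglycone: {res.aglycone}")
# salicin keeps its salicyl alcohol skeleton; the pure sugar vanishes
# entirely (sugar_only) and would be dropped from a cohort
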