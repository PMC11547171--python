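"""Chemical-space embeddings: property PCA, MST tree map, metric embedding.

PCA variance fractions say how much structure two axes capture; the MST tree
map and the classical metric embedding lay out ring assemblies by fingerprint
Jaccard distance.
"""

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from chronochem import (
    GeneratorConfig,
    compute_descriptors,
    generate_cohorts,
    nonlinear_map,
    pca_properties,
    tree_map,
)
from chronochem.chemspace import jaccard_distance_matrix
from chronochem.descriptors import SCALAR_FIELDS

cohorts = generate_cohorts(GeneratorConfig(n_per_cohort=150, group_size=50, seed=30))
records = cohorts.np_records + cohorts.sc_records
matrix = np.array(
    [
        [
            getattr(compute_descriptors(Chem.MolFromSmiles(r.structure), with_shape=False), f)
            for f in SCALAR_FIELDS
        ]
        for r in records
    ]
)
emb = pca_properties(matrix, color_key=[r.cohort.value for r in records])
print(f"property PCA: PC1 {emb.explained_variance[0]:.1%}, "
      f"PC2 {emb.explained_variance[1]:.1%} of descriptor variance")

assemblies = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCC2CCCCC2C1", "C1CCC2(CC1)CCCC2"]
fps = np.array([np.array(MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(s))) for s in assemblies])
tm = tree_map(assemblies, fps, seed=1)
print(f"\nMST over {len(assemblies)} ring assemblies ({len(tm.edges)} edges):")
for i, j, w in tm.edges:
    print(f"  {assemblies[i]:16s} -- {assemblies[j]:16s} Jaccard distance {w:.3f}")
# chemically similar assemblies join with short edges (benzene-pyridine)

nlm = nonlinear_map(jaccard_distance_matrix(fps))
print("\nmetric embedding coordinates (2D):")
for s, (x, y) in zip(assemblies, nlm.coordinates):
    print(f"  {s:16s} ({x:+.3f}, {y:+.3f})")
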