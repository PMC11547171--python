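"""Natural-product-likeness scoring and biorelevance (BR) similarity.

NP-likeness is a retrainable fragment-contribution score: circular
atom-centred environments of radius <= 2 are counted over an NP training
corpus and an SC training corpus, and each environment ``f`` gets

    contribution(f) = log10( ((c_NP(f)+1)/T_NP) / ((c_SC(f)+1)/T_SC) )

with Laplace +1 smoothing and T the total environment occurrences of each
corpus.  A molecule's score is the sum of contributions of its environments
divided by its heavy-atom count, clipped to [-5, 5]: positive means the
molecule's substructures are more at home among natural products.

The BR score is the maximum Tanimoto similarity of a molecule's radius-2
2048-bit circular fingerprint to a reference set of biologically relevant
structures (user- or generator-supplied).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

RADIUS = 2
N_BITS = 2048
CLIP = 5.0

_count_gen = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS)
_bit_gen = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


def _as_mol(structure: "str | Chem.Mol") -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure {structure!r}")
    return mol


def environment_counts(mol: Chem.Mol) -> dict[int, int]:
    """Counts of canonical atom-centred environments (radius 0..2)."""
    fp = _count_gen.GetSparseCountFingerprint(mol)
    return dict(fp.GetNonzeroElements())


@dataclass
class ContributionTable:
    c_np: dict[int, int] = field(default_factory=dict)
    c_sc: dict[int, int] = field(default_factory=dict)
    t_np: int = 0
    t_sc: int = 0

    def contribution(self, fragment: int) -> float:
        if fragment not in self.c_np and fragment not in self.c_sc:
            return 0.0
        p_np = (self.c_np.get(fragment, 0) + 1) / self.t_np
        p_sc = (self.c_sc.get(fragment, 0) + 1) / self.t_sc
        return math.log10(p_np / p_sc)

    def to_json(self, path: str | Path) -> None:
        keys = sorted(set(self.c_np) | set(self.c_sc))
        payload = {
            "t_np": self.t_np,
            "t_sc": self.t_sc,
            "fragments": {
                str(k): {
                    "c_np": self.c_np.get(k, 0),
                    "c_sc": self.c_sc.get(k, 0),
                    "contribution": self.contribution(k),
                }
                for k in keys
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContributionTable":
        payload = json.loads(Path(path).read_text())
        c_np = {int(k): v["c_np"] for k, v in payload["fragments"].items() if v["c_np"]}
        c_sc = {int(k): v["c_sc"] for k, v in payload["fragments"].items() if v["c_sc"]}
        return cls(c_np=c_np, c_sc=c_sc, t_np=payload["t_np"], t_sc=payload["t_sc"])


def train_np_likeness(
    np_training: Sequence["str | Chem.Mol"], sc_training: Sequence["str | Chem.Mol"]
) -> ContributionTable:
    if not np_training or not sc_training:
        raise ValueError("both training sets must be non-empty")
    table = ContributionTable()
    for structure in np_training:
        for frag, n in environment_counts(_as_mol(structure)).items():
            table.c_np[frag] = table.c_np.get(frag, 0) + n
            table.t_np += n
    for structure in sc_training:
        for frag, n in environment_counts(_as_mol(structure)).items():
            table.c_sc[frag] = table.c_sc.get(frag, 0) + n
            table.t_sc += n
    return table


def np_likeness_score(structure: "str | Chem.Mol", table: ContributionTable) -> float:
    mol = _as_mol(structure)
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy == 0:
        raise ValueError("molecule has no heavy atoms")
    total = sum(
        n * table.contribution(frag) for frag, n in environment_counts(mol).items()
    )
    return max(-CLIP, min(CLIP, total / n_heavy))


def fingerprint(structure: "str | Chem.Mol"):
    """Radius-2 2048-bit circular fingerprint bit vector."""
    return _bit_gen.GetFingerprint(_as_mol(structure))


def reference_fingerprints(structures: Iterable["str | Chem.Mol"]) -> list:
    return [fingerprint(s) for s in structures]


def br_score(structure: "str | Chem.Mol", reference_fps: Sequence) -> float:
    """Maximum Tanimoto similarity to the biorelevant reference set."""
    if not reference_fps:
        raise ValueError("reference set must be non-empty")
    sims = DataStructs.BulkTanimotoSimilarity(fingerprint(structure), list(reference_fps))
    return max(sims)
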