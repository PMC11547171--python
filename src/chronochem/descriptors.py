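"""Physicochemical descriptor panel.

The panel groups size (MW, volume, surface area, atom/bond counts), rings
(counts, assemblies, aromaticity, ring-size bins), polarity (AlogP, log
aqueous solubility, TPSA, H-bond donors/acceptors), complexity (stereo
centres/bonds, sp3 carbon count, rotatable bonds, globularity) and elemental
composition (halogens, N, O, S, P).

AlogP is the Crippen atomic-contribution octanol–water partition coefficient;
TPSA the Ertl fragment sum; log solubility the ESOL linear model
``logS = 0.16 - 0.63*clogP - 0.0062*MW + 0.066*RB - 0.74*AP`` with AP the
aromatic-atom proportion.  Shape descriptors come from a single seeded ETKDG
conformer: volume by grid integration over van-der-Waals spheres, surface area
by the Shrake–Rupley method, and globularity as the smallest-to-largest
eigenvalue ratio of the heavy-atom gyration tensor (0 = linear/planar,
1 = spherical).  logD is deliberately not part of the panel: it requires pKa
prediction, which is outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdFreeSASA, rdMolDescriptors

from .fragments import ring_assemblies

DEFAULT_CONFORMER_SEED = 2016

SCALAR_FIELDS: tuple[str, ...] = (
    "mol_weight",
    "n_heavy_atoms",
    "n_bonds",
    "n_rings",
    "n_ring_assemblies",
    "n_aromatic_rings",
    "n_nonaromatic_rings",
    "n_ring3",
    "n_ring4",
    "n_ring5",
    "n_ring6",
    "n_ring7",
    "n_ring8plus",
    "alogp",
    "log_solubility",
    "tpsa",
    "n_hba",
    "n_hbd",
    "n_stereo_atoms",
    "n_stereo_bonds",
    "n_chiral_centers",
    "n_csp3",
    "n_rotatable_bonds",
    "n_F",
    "n_Cl",
    "n_Br",
    "n_I",
    "n_N",
    "n_O",
    "n_S",
    "n_P",
)

SHAPE_FIELDS: tuple[str, ...] = ("mol_volume", "mol_surface_area", "globularity")


@dataclass
class DescriptorVector:
    record_id: str
    mol_weight: float
    n_heavy_atoms: int
    n_bonds: int
    n_rings: int
    n_ring_assemblies: int
    n_aromatic_rings: int
    n_nonaromatic_rings: int
    n_ring3: int
    n_ring4: int
    n_ring5: int
    n_ring6: int
    n_ring7: int
    n_ring8plus: int
    alogp: float
    log_solubility: float
    tpsa: float
    n_hba: int
    n_hbd: int
    n_stereo_atoms: int
    n_stereo_bonds: int
    n_chiral_centers: int
    n_csp3: int
    n_rotatable_bonds: int
    n_F: int
    n_Cl: int
    n_Br: int
    n_I: int
    n_N: int
    n_O: int
    n_S: int
    n_P: int
    mol_volume: float | None = None
    mol_surface_area: float | None = None
    globularity: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def ring_profile(mol: Chem.Mol) -> dict[str, int]:
    """Ring counts from the smallest set of smallest rings; a ring is aromatic
    iff all its bonds are aromatic; assemblies merge rings sharing an atom."""
    ri = mol.GetRingInfo()
    n_aromatic = sum(
        1
        for ring in ri.BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )
    sizes = [len(r) for r in ri.AtomRings()]
    bins = {k: 0 for k in range(3, 8)}
    n8 = 0
    for s in sizes:
        if s >= 8:
            n8 += 1
        else:
            bins[s] += 1
    return {
        "n_rings": ri.NumRings(),
        "n_ring_assemblies": sum(ring_assemblies(mol).values()),
        "n_aromatic_rings": n_aromatic,
        "n_nonaromatic_rings": ri.NumRings() - n_aromatic,
        "n_ring3": bins[3],
        "n_ring4": bins[4],
        "n_ring5": bins[5],
        "n_ring6": bins[6],
        "n_ring7": bins[7],
        "n_ring8plus": n8,
    }


def esol_log_solubility(mol: Chem.Mol) -> float:
    """ESOL estimated log10 aqueous solubility (mol/L)."""
    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    )
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def polarity_profile(mol: Chem.Mol) -> dict[str, float]:
    return {
        "alogp": Crippen.MolLogP(mol),
        "log_solubility": esol_log_solubility(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "n_hba": rdMolDescriptors.CalcNumLipinskiHBA(mol),
        "n_hbd": rdMolDescriptors.CalcNumLipinskiHBD(mol),
    }


def complexity_profile(mol: Chem.Mol) -> dict[str, int]:
    """Stereo atoms count potential tetrahedral centres (assigned or not);
    chiral centres count assigned only; stereo bonds are double bonds with
    distinguishable substituent pairs."""
    stereo_atoms = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    chiral = [c for c in stereo_atoms if c[1] in ("R", "S")]
    si = Chem.FindPotentialStereo(mol)
    n_stereo_bonds = sum(
        1 for e in si if e.type == Chem.StereoType.Bond_Double
    )
    n_csp3 = sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP3
    )
    return {
        "n_stereo_atoms": len(stereo_atoms),
        "n_stereo_bonds": n_stereo_bonds,
        "n_chiral_centers": len(chiral),
        "n_csp3": n_csp3,
        "n_rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
    }


def element_profile(mol: Chem.Mol) -> dict[str, float]:
    counts = {"F": 0, "Cl": 0, "Br": 0, "I": 0, "N": 0, "O": 0, "S": 0, "P": 0}
    for a in mol.GetAtoms():
        s = a.GetSymbol()
        if s in counts:
            counts[s] += 1
    return {
        "n_F": counts["F"],
        "n_Cl": counts["Cl"],
        "n_Br": counts["Br"],
        "n_I": counts["I"],
        "n_N": counts["N"],
        "n_O": counts["O"],
        "n_S": counts["S"],
        "n_P": counts["P"],
        "n_heavy_atoms": mol.GetNumHeavyAtoms(),
        "n_bonds": mol.GetNumBonds(),
        "mol_weight": Descriptors.MolWt(mol),
    }


def globularity_from_coords(coords: np.ndarray) -> float:
    """lambda_min / lambda_max of the gyration tensor, clamped to [0, 1]."""
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / len(centered)
    eig = np.linalg.eigvalsh(gyr)
    if eig[-1] <= 0:
        return 0.0
    return float(min(max(eig[0] / eig[-1], 0.0), 1.0))


def shape_profile(
    mol: Chem.Mol, seed: int = DEFAULT_CONFORMER_SEED
) -> dict[str, float | None]:
    """3D shape descriptors from one seeded conformer; all-None on embedding
    failure (the molecule is then excluded from those group means only)."""
    m3 = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(m3, params) != 0:
        return {"mol_volume": None, "mol_surface_area": None, "globularity": None}
    volume = AllChem.ComputeMolVolume(m3)  # 0.2 A grid over vdW spheres
    radii = rdFreeSASA.classifyAtoms(m3)
    sasa = rdFreeSASA.CalcSASA(m3, radii)
    conf = m3.GetConformer()
    heavy = [
        conf.GetAtomPosition(a.GetIdx()) for a in m3.GetAtoms() if a.GetAtomicNum() > 1
    ]
    coords = np.array([[p.x, p.y, p.z] for p in heavy])
    return {
        "mol_volume": float(volume),
        "mol_surface_area": float(sasa),
        "globularity": globularity_from_coords(coords),
    }


def compute_descriptors(
    mol: Chem.Mol,
    record_id: str = "",
    with_shape: bool = True,
    seed: int = DEFAULT_CONFORMER_SEED,
) -> DescriptorVector:
    vals: dict = {}
    vals.update(element_profile(mol))
    vals.update(ring_profile(mol))
    vals.update(polarity_profile(mol))
    vals.update(complexity_profile(mol))
    if with_shape:
        vals.update(shape_profile(mol, seed=seed))
    return DescriptorVector(record_id=record_id, **vals)
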