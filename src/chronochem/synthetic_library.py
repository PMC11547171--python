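"""Synthetic NP-like and SC-like cohort generator.

The real inputs of the analysis — a natural-product dictionary and a merged
vendor collection, both CAS-annotated — are commercial.  This module builds
two chronologically ordered stand-in cohorts from a small building-block
grammar, with the structural contrasts the downstream statistics are
sensitive to:

* NP-like: fused/spiro/bridged aliphatic ring cores, oxygen-rich substituents,
  randomly assigned stereocentres, and pyranose units attached through
  O-glycosidic bonds at a configured fraction; the per-group target molecular
  weight drifts upward to emulate the historical growth of natural products.
* SC-like: aromatic monocycles joined by amide/amine/sulfonamide/ether/biaryl
  linkers, halogen decoration, and a drug-like size window.

Pseudo-CAS Registry Numbers are allocated strictly increasing with simulated
time, interleaved between the cohorts, and always carry a valid check digit.
The grammar makes no claim of synthesizability — only the distributional
contrasts matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import CompoundRecord, Cohort, cas_check_digit

NP_CORES: tuple[str, ...] = (
    "C1CCC2CCCCC2C1",        # decalin (fused)
    "C1CCC2CCCC2C1",         # hydrindane (fused)
    "C1CCC2(CC1)CCCC2",      # spiro[4.5]decane
    "C1CC2CCC1C2",           # norbornane (bridged)
    "C1CC2CCC1CC2",          # bicyclo[2.2.2]octane
    "C1CCC2C(C1)CCC1CCCCC12",  # perhydrophenanthrene (3 fused rings)
    "CC12CCC3C(CCC4CCCCC43)C1CCC2",  # steroid-like tetracycle
)
NP_SIMPLE_CORES: tuple[str, ...] = ("C1CCCCC1", "C1CCCC1", "C1CCCCCC1")
#: substituents; the first atom of each SMILES is the attachment atom
NP_SUBSTITUENTS: tuple[str, ...] = (
    "O", "O", "CO", "C", "C(C)O", "OC(C)=O", "C(=O)O", "CC", "CCO", "C(C)C",
)
PYRANOSE = "OC1OC(CO)C(O)C(O)C1O"  # glycosidic O first: attaches to the aglycone

SC_AROMATIC_CORES: tuple[str, ...] = (
    "c1ccccc1", "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1",
)
SC_ALIPHATIC_CORES: tuple[str, ...] = ("C1CCCCC1", "C1CCNCC1", "C1CCOCC1")
SC_SUBSTITUENTS: tuple[str, ...] = (
    "C", "OC", "C#N", "C(F)(F)F", "N(C)C", "C(C)=O", "N", "OCC",
)
SC_HALOGENS: tuple[str, ...] = ("F", "Cl", "Cl", "Br")
#: linker templates joining two cores: SMILES inserted between attachment atoms
SC_LINKERS: tuple[str, ...] = ("C(=O)N", "N", "S(=O)(=O)N", "O", "")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohorts.

    Defaults: 5000 molecules per cohort in 10 chronological groups of 500; a
    0.16 glycosylation fraction for the NP-like cohort (the reported share of
    glycosylated natural products); NP molecular weight drifting +6 Da per
    group, emulating the historical upward drift; strong fused-ring bias for
    NP-like and aromatic bias for SC-like structures.
    """

    n_per_cohort: int = 5000
    group_size: int = 500
    seed: int = 2016
    glycosylation_fraction: float = 0.16
    mean_sugars_per_glycoside: float = 1.5
    mw_drift: float = 6.0
    np_fused_ring_bias: float = 0.7
    sc_aromatic_bias: float = 0.9
    halogen_prob_sc: float = 0.35
    reference_set_size: int = 100
    np_mw_base: float = 280.0

    def __post_init__(self):
        for name in (
            "glycosylation_fraction",
            "np_fused_ring_bias",
            "sc_aromatic_bias",
            "halogen_prob_sc",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise GenerationError(f"{name} must lie in [0, 1]")
        if self.mean_sugars_per_glycoside < 1:
            raise GenerationError("mean_sugars_per_glycoside must be >= 1")
        if self.n_per_cohort < self.group_size:
            raise GenerationError("n_per_cohort must be >= group_size")
        n_groups = self.n_per_cohort // self.group_size
        if self.np_mw_base + self.mw_drift * max(n_groups - 1, 0) > 1800:
            raise GenerationError(
                "mw_drift: per-group target molecular weight exceeds the "
                "building-block range (max 1800 Da)"
            )


def _attach(core: Chem.Mol, sub_smiles: str, rng: np.random.Generator) -> Chem.Mol:
    """Bond the first atom of ``sub_smiles`` to a random carbon of ``core``
    with a free valence; returns ``core`` unchanged if no site works."""
    sub = Chem.MolFromSmiles(sub_smiles)
    sites = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]
    if not sites:
        return core
    rng.shuffle(sites)
    for site in sites:
        combined = Chem.RWMol(Chem.CombineMols(core, sub))
        combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
        try:
            out = combined.GetMol()
            Chem.SanitizeMol(out)
            return out
        except Exception:
            continue
    return core


def _assign_random_stereo(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    for idx, label in centers:
        if label == "?":
            tag = (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW
                if rng.random() < 0.5
                else Chem.ChiralType.CHI_TETRAHEDRAL_CCW
            )
            mol.GetAtomWithIdx(idx).SetChiralTag(tag)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def _np_molecule(
    rng: np.random.Generator,
    config: GeneratorConfig,
    target_mw: float,
    glycoside: bool,
) -> tuple[str, int]:
    """One NP-like SMILES and its number of attached sugar rings."""
    if rng.random() < config.np_fused_ring_bias:
        core_smiles = NP_CORES[rng.integers(len(NP_CORES))]
    else:
        core_smiles = NP_SIMPLE_CORES[rng.integers(len(NP_SIMPLE_CORES))]
    mol = Chem.MolFromSmiles(core_smiles)
    n_sugars = 0
    if glycoside:
        n_sugars = 1 + int(rng.poisson(config.mean_sugars_per_glycoside - 1))
        for _ in range(n_sugars):
            mol = _attach(mol, PYRANOSE, rng)
    # fill toward the group's target weight with O-rich decorations
    for _ in range(40):
        if Descriptors.MolWt(mol) >= target_mw - 20:
            break
        mol = _attach(mol, NP_SUBSTITUENTS[rng.integers(len(NP_SUBSTITUENTS))], rng)
    mol = _assign_random_stereo(mol, rng)
    return Chem.MolToSmiles(mol), n_sugars


def _sc_molecule(rng: np.random.Generator, config: GeneratorConfig) -> str:
    aromatic = rng.random() < config.sc_aromatic_bias
    pool = SC_AROMATIC_CORES if aromatic else SC_ALIPHATIC_CORES
    mol = Chem.MolFromSmiles(pool[rng.integers(len(pool))])
    if rng.random() < 0.6:  # second ring through a linker
        linker = SC_LINKERS[rng.integers(len(SC_LINKERS))]
        second = pool[rng.integers(len(pool))]
        mol = _attach(mol, linker + second, rng)
    n_halogen = rng.binomial(3, config.halogen_prob_sc)
    for _ in range(n_halogen):
        mol = _attach(mol, SC_HALOGENS[rng.integers(len(SC_HALOGENS))], rng)
    for _ in range(rng.integers(1, 4)):
        mol = _attach(mol, SC_SUBSTITUENTS[rng.integers(len(SC_SUBSTITUENTS))], rng)
    return Chem.MolToSmiles(mol)


def _cas(seq: int, offset: int, stride: int = 2) -> str:
    serial = offset + seq * stride
    major, minor = 50 + serial // 100, serial % 100
    return f"{major}-{minor:02d}-{cas_check_digit(major, minor)}"


@dataclass
class SyntheticCohorts:
    np_records: list[CompoundRecord]
    sc_records: list[CompoundRecord]
    reference_structures: list[str]
    n_sugars_attached: dict[str, int] = field(default_factory=dict)


def generate_cohorts(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCohorts:
    """Generate both cohorts plus a biorelevant reference set.

    Deterministic for a fixed config (byte-identical SMILES and CAS).  CAS
    keys are strictly increasing within each cohort and interleaved between
    cohorts, so cross-cohort first-occurrence comparisons are meaningful.
    """
    rng = np.random.default_rng(config.seed)
    np_records: list[CompoundRecord] = []
    sc_records: list[CompoundRecord] = []
    sugars: dict[str, int] = {}
    for i in range(config.n_per_cohort):
        group_idx = i // config.group_size
        target = config.np_mw_base + config.mw_drift * group_idx
        glycoside = bool(rng.random() < config.glycosylation_fraction)
        smiles, n_sug = _np_molecule(rng, config, target, glycoside)
        rid = f"NP:{i}"
        np_records.append(
            CompoundRecord(structure=smiles, cas=_cas(i, 0), cohort=Cohort.NP, record_id=rid)
        )
        sugars[rid] = n_sug
        sc_records.append(
            CompoundRecord(
                structure=_sc_molecule(rng, config),
                cas=_cas(i, 1),
                cohort=Cohort.SC,
                record_id=f"SC:{i}",
            )
        )
    ref_rng = np.random.default_rng(config.seed + 1)
    reference = [
        _np_molecule(ref_rng, config, config.np_mw_base, ref_rng.random() < 0.3)[0]
        for _ in range(config.reference_set_size)
    ]
    return SyntheticCohorts(
        np_records=np_records,
        sc_records=sc_records,
        reference_structures=reference,
        n_sugars_attached=sugars,
    )


@dataclass(frozen=True)
class FixtureMolecule:
    name: str
    smiles: str
    expected: dict


def emit_fixture_molecules() -> dict[str, FixtureMolecule]:
    """Hand-auditable worked-example molecules with expected per-module
    outputs; every fixture standardizes to kept."""
    fixtures = [
        FixtureMolecule(
            "salicin",
            "OCc1ccccc1OC1OC(CO)C(O)C(O)C1O",
            {"n_sugar_rings_removed": 1, "sugar_only": False},
        ),
        FixtureMolecule(
            "methyl_glucopyranoside",
            "COC1OC(CO)C(O)C(O)C1O",
            {"n_sugar_rings_removed": 1, "sugar_only": False, "aglycone": "CO"},
        ),
        FixtureMolecule(
            "xylopyranose",
            "OC1COC(O)C(O)C1O",
            {"n_sugar_rings_removed": 1, "sugar_only": True},
        ),
        FixtureMolecule(
            "tetrahydropyran", "C1CCOCC1", {"n_sugar_rings_removed": 0}
        ),
        FixtureMolecule("cyclohexane", "C1CCCCC1", {"n_sugar_rings_removed": 0, "n_rings": 1, "n_aromatic_rings": 0}),
        FixtureMolecule("cyclohexanol", "OC1CCCCC1", {"n_sugar_rings_removed": 0}),
        FixtureMolecule(
            "toluene", "Cc1ccccc1", {"scaffold": "c1ccccc1", "side_chains": {"*C": 1}}
        ),
        FixtureMolecule("benzene", "c1ccccc1", {"scaffold": "c1ccccc1", "side_chains": {}, "tpsa": 0.0}),
        FixtureMolecule(
            "p_cresol", "Cc1ccc(O)cc1", {"side_chains": {"*C": 1, "*O": 1}}
        ),
        FixtureMolecule(
            "naphthalene", "c1ccc2ccccc2c1", {"n_rings": 2, "n_ring_assemblies": 1, "n_aromatic_rings": 2}
        ),
        FixtureMolecule(
            "biphenyl", "c1ccc(-c2ccccc2)cc1", {"n_rings": 2, "n_ring_assemblies": 2}
        ),
        FixtureMolecule(
            "diphenylmethane",
            "C(c1ccccc1)c1ccccc1",
            {"scaffold_heavy_atoms": 13},  # linker CH2 retained
        ),
        FixtureMolecule(
            "spiro45decane",
            "C1CCC2(CC1)CCCC2",
            {"n_ring_assemblies": 1, "n_spiro_atoms": 1, "n_bridgehead_atoms": 0},
        ),
        FixtureMolecule(
            "norbornane",
            "C1CC2CCC1C2",
            {"n_ring_assemblies": 1, "n_spiro_atoms": 0, "n_bridgehead_atoms": 2},
        ),
        FixtureMolecule(
            "acetanilide",
            "CC(=O)Nc1ccccc1",
            {"recap_n_kept": 1, "scaffold": "c1ccccc1"},
        ),
        FixtureMolecule(
            "n_benzylaniline", "C(Nc1ccccc1)c1ccccc1", {"recap_n_kept": 2}
        ),
        FixtureMolecule("chlorobenzene", "Clc1ccccc1", {"n_Cl": 1, "n_heavy_atoms": 7}),
        FixtureMolecule("trifluorotoluene", "FC(F)(F)c1ccccc1", {"n_F": 3}),
    ]
    return {f.name: f for f in fixtures}
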