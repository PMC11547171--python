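"""Scaffolds, ring assemblies, side chains, RECAP fragments."""

import pytest
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from chronochem.fragments import (
    assembly_profile,
    decompose,
    murcko_scaffold,
    recap_fragments,
    ring_assemblies,
    side_chains,
)


def mol(smiles):
    return Chem.MolFromSmiles(smiles)


def heavy_atoms_no_marker(smiles: str) -> int:
    m = Chem.MolFromSmiles(smiles)
    return sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 0)


class TestScaffold:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("Cc1ccccc1", "c1ccccc1"),
            ("CCCCCC", None),
            ("CC(=O)Nc1ccccc1", "c1ccccc1"),
        ],
    )
    def test_examples(self, smiles, expected):
        assert murcko_scaffold(mol(smiles)) == expected

    def test_diphenylmethane_keeps_linker(self):
        s = murcko_scaffold(mol("C(c1ccccc1)c1ccccc1"))
        assert Chem.MolFromSmiles(s).GetNumHeavyAtoms() == 13

    def test_exocyclic_double_bond_retained(self):
        assert murcko_scaffold(mol("O=C1CCCCC1C")) == "O=C1CCCCC1"

    def test_idempotent(self, fixture_mols):
        for name, m in fixture_mols.items():
            s = murcko_scaffold(m)
            if s is None:
                continue
            assert murcko_scaffold(Chem.MolFromSmiles(s)) == s, name

    def test_agrees_with_reference_implementation(self, fixture_mols, small_cohorts):
        """Independent oracle: RDKit's own Murcko scaffold extraction."""
        structures = [m for m in fixture_mols.values()]
        structures += [mol(r.structure) for r in small_cohorts.sc_records[:50]]
        for m in structures:
            ours = murcko_scaffold(m)
            ref = MurckoScaffold.GetScaffoldForMol(m)
            theirs = Chem.MolToSmiles(ref) if ref.GetNumAtoms() else None
            assert ours == theirs, Chem.MolToSmiles(m)


class TestRingAssemblies:
    def test_biphenyl_two_assemblies(self):
        assert ring_assemblies(mol("c1ccc(-c2ccccc2)cc1")) == {"c1ccccc1": 2}

    def test_naphthalene_one_assembly(self):
        assert sum(ring_assemblies(mol("c1ccc2ccccc2c1")).values()) == 1

    def test_spiro_merges(self):
        out = ring_assemblies(mol("C1CCC2(CC1)CCCC2"))
        assert sum(out.values()) == 1

    def test_acyclic_empty(self):
        assert ring_assemblies(mol("CCOCC")) == {}

    def test_ring_counts_partition(self, fixture_mols):
        """Sum of per-assembly ring counts equals the molecule ring count."""
        for name, m in fixture_mols.items():
            total = 0
            for smiles, count in ring_assemblies(m).items():
                total += assembly_profile(Chem.MolFromSmiles(smiles))["n_rings"] * count
            assert total == m.GetRingInfo().NumRings(), name


class TestAssemblyProfile:
    def test_spiro_decane(self):
        p = assembly_profile(mol("C1CCC2(CC1)CCCC2"))
        assert p["n_spiro_atoms"] == 1 and p["n_bridgehead_atoms"] == 0

    def test_norbornane(self):
        p = assembly_profile(mol("C1CC2CCC1C2"))
        assert p["n_spiro_atoms"] == 0 and p["n_bridgehead_atoms"] == 2

    def test_benzene(self):
        p = assembly_profile(mol("c1ccccc1"))
        assert p["n_spiro_atoms"] == 0 and p["n_bridgehead_atoms"] == 0
        assert p["n_rings"] == 1 and p["n_aromatic_rings"] == 1


class TestSideChains:
    def test_toluene(self):
        assert side_chains(mol("Cc1ccccc1")) == {"*C": 1}

    def test_benzene_empty(self):
        assert side_chains(mol("c1ccccc1")) == {}

    def test_p_cresol(self):
        assert side_chains(mol("Cc1ccc(O)cc1")) == {"*C": 1, "*O": 1}

    def test_acyclic_empty(self):
        assert side_chains(mol("CCCCO")) == {}

    def test_one_marker_each(self, small_cohorts):
        for rec in small_cohorts.np_records[:40]:
            for smiles in side_chains(mol(rec.structure)):
                m = Chem.MolFromSmiles(smiles)
                assert sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0) == 1

    def test_heavy_atom_conservation(self, fixture_mols, small_cohorts):
        """scaffold heavy atoms + side-chain heavy atoms = molecule heavy
        atoms (markers excluded)."""
        mols = list(fixture_mols.values())
        mols += [mol(r.structure) for r in small_cohorts.np_records[:40]]
        mols += [mol(r.structure) for r in small_cohorts.sc_records[:40]]
        for m in mols:
            scaffold = murcko_scaffold(m)
            if scaffold is None:
                continue
            n = Chem.MolFromSmiles(scaffold).GetNumHeavyAtoms()
            for smiles, count in side_chains(m).items():
                n += heavy_atoms_no_marker(smiles) * count
            assert n == m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)


class TestRecap:
    def test_acetanilide_filters_small_acyl(self):
        out = recap_fragments(mol("CC(=O)Nc1ccccc1"), min_heavy=4)
        assert list(out) == ["*Nc1ccccc1"]  # 3-heavy acetyl piece filtered

    def test_cyclohexane_uncleavable(self):
        assert recap_fragments(mol("C1CCCCC1")) == {}

    def test_benzylaniline_two_fragments(self):
        out = recap_fragments(mol("C(Nc1ccccc1)c1ccccc1"))
        assert sum(out.values()) == 2
        assert all(heavy_atoms_no_marker(s) >= 4 for s in out)

    def test_fragments_are_substructures(self, small_cohorts):
        for rec in small_cohorts.sc_records[:30]:
            m = mol(rec.structure)
            for smiles in recap_fragments(m):
                core = Chem.DeleteSubstructs(
                    Chem.MolFromSmiles(smiles), Chem.MolFromSmiles("[#0]")
                )
                assert m.HasSubstructMatch(core), (rec.structure, smiles)

    def test_filter_monotone_in_min_heavy(self, small_cohorts):
        for rec in small_cohorts.sc_records[:30]:
            m = mol(rec.structure)
            sizes = [sum(recap_fragments(m, k).values()) for k in (1, 4, 8)]
            assert sizes == sorted(sizes, reverse=True)


def test_decompose_bundles_all_four(fixture_mols):
    fs = decompose(fixture_mols["toluene"], "toluene")
    assert fs.scaffold == "c1ccccc1"
    assert fs.side_chains == {"*C": 1}
    assert sum(fs.ring_assemblies.values()) == 1


def test_acyclic_has_no_scaffold_assemblies_or_chains():
    fs = decompose(mol("CCOC(C)=O"), "ester")
    assert fs.scaffold is None
    assert fs.ring_assemblies == {} and fs.side_chains == {}
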