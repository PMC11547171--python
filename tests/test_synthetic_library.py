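"""Synthetic cohort generator: determinism, CAS validity, programmed contrasts."""

import numpy as np
import pytest
from rdkit import Chem

from chronochem.chem_io import parse_cas, standardize
from chronochem.deglyco import remove_sugars
from chronochem.descriptors import ring_profile
from chronochem.synthetic_library import (
    GenerationError,
    GeneratorConfig,
    emit_fixture_molecules,
    generate_cohorts,
)


class TestGenerateCohorts:
    def test_deterministic(self):
        cfg = GeneratorConfig(n_per_cohort=60, group_size=20, seed=5)
        a, b = generate_cohorts(cfg), generate_cohorts(cfg)
        assert [r.structure for r in a.np_records] == [r.structure for r in b.np_records]
        assert [r.cas for r in a.sc_records] == [r.cas for r in b.sc_records]
        assert a.reference_structures == b.reference_structures

    def test_cas_strictly_increasing_and_valid(self, small_cohorts):
        for records in (small_cohorts.np_records, small_cohorts.sc_records):
            keys = [parse_cas(r.cas) for r in records]
            assert all(k.checksum_valid for k in keys)
            assert all(a.sort_key < b.sort_key for a, b in zip(keys, keys[1:]))

    def test_zero_glycosylation_fraction(self):
        c = generate_cohorts(
            GeneratorConfig(n_per_cohort=50, group_size=10, seed=3, glycosylation_fraction=0)
        )
        for r in c.np_records:
            assert remove_sugars(Chem.MolFromSmiles(r.structure)).n_sugar_rings_removed == 0

    def test_all_structures_parse_and_standardize(self, small_cohorts):
        for r in small_cohorts.np_records + small_cohorts.sc_records:
            assert standardize(r).kept, r.structure

    def test_ring_contrast(self, small_cohorts):
        """NP-like molecules carry more non-aromatic rings; SC-like more
        aromatic rings (the programmed structural contrast)."""
        def means(records):
            arom, nonarom = [], []
            for r in records:
                p = ring_profile(Chem.MolFromSmiles(r.structure))
                arom.append(p["n_aromatic_rings"])
                nonarom.append(p["n_nonaromatic_rings"])
            return np.mean(arom), np.mean(nonarom)

        np_arom, np_nonarom = means(small_cohorts.np_records)
        sc_arom, sc_nonarom = means(small_cohorts.sc_records)
        assert np_nonarom > sc_nonarom
        assert sc_arom > np_arom

    def test_reference_set_size(self, small_cohorts):
        assert len(small_cohorts.reference_structures) == 25
        for s in small_cohorts.reference_structures:
            assert Chem.MolFromSmiles(s) is not None

    def test_unsatisfiable_mw_drift_raises(self):
        with pytest.raises(GenerationError, match="mw_drift"):
            GeneratorConfig(n_per_cohort=5000, group_size=50, mw_drift=40.0)

    def test_invalid_probability_raises(self):
        with pytest.raises(GenerationError):
            GeneratorConfig(glycosylation_fraction=1.5)


class TestFixtures:
    def test_at_least_fifteen(self, fixtures):
        assert len(fixtures) >= 15

    def test_all_parse_and_standardize_kept(self, fixtures):
        from chronochem.chem_io import CompoundRecord, Cohort

        for f in fixtures.values():
            assert Chem.MolFromSmiles(f.smiles) is not None, f.name
            rec = CompoundRecord(f.smiles, "50-00-0", Cohort.NP, f.name)
            assert standardize(rec).kept, f.name

    def test_salicin_expectation_encoded(self, fixtures):
        assert fixtures["salicin"].expected["n_sugar_rings_removed"] == 1

    def test_expected_values_hold(self, fixtures, fixture_mols):
        """Each fixture's encoded expectations match the modules' outputs."""
        from chronochem.descriptors import element_profile, polarity_profile
        from chronochem.fragments import (
            assembly_profile,
            murcko_scaffold,
            recap_fragments,
            ring_assemblies,
            side_chains,
        )

        for name, f in fixtures.items():
            mol = fixture_mols[name]
            exp = f.expected
            if "n_sugar_rings_removed" in exp:
                res = remove_sugars(mol)
                assert res.n_sugar_rings_removed == exp["n_sugar_rings_removed"], name
                if "sugar_only" in exp:
                    assert res.sugar_only == exp["sugar_only"], name
                if "aglycone" in exp:
                    assert res.aglycone == exp["aglycone"], name
            if "scaffold" in exp:
                assert murcko_scaffold(mol) == exp["scaffold"], name
            if "scaffold_heavy_atoms" in exp:
                s = Chem.MolFromSmiles(murcko_scaffold(mol))
                assert s.GetNumHeavyAtoms() == exp["scaffold_heavy_atoms"], name
            if "side_chains" in exp:
                assert dict(side_chains(mol)) == exp["side_chains"], name
            if "n_rings" in exp:
                assert ring_profile(mol)["n_rings"] == exp["n_rings"], name
            if "n_ring_assemblies" in exp:
                assert (
                    ring_profile(mol)["n_ring_assemblies"] == exp["n_ring_assemblies"]
                ), name
            if "n_aromatic_rings" in exp:
                assert ring_profile(mol)["n_aromatic_rings"] == exp["n_aromatic_rings"]
            if "n_spiro_atoms" in exp:
                p = assembly_profile(mol)
                assert p["n_spiro_atoms"] == exp["n_spiro_atoms"], name
                assert p["n_bridgehead_atoms"] == exp["n_bridgehead_atoms"], name
            if "recap_n_kept" in exp:
                assert sum(recap_fragments(mol).values()) == exp["recap_n_kept"], name
            if "tpsa" in exp:
                assert polarity_profile(mol)["tpsa"] == pytest.approx(exp["tpsa"]), name
            for key in ("n_Cl", "n_F", "n_heavy_atoms"):
                if key in exp:
                    assert element_profile(mol)[key] == exp[key], name
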