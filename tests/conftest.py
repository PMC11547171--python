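import pytest
from rdkit import Chem

from chronochem.synthetic_library import (
    GeneratorConfig,
    emit_fixture_molecules,
    generate_cohorts,
)


@pytest.fixture(scope="session")
def fixtures():
    return emit_fixture_molecules()


@pytest.fixture(scope="session")
def fixture_mols(fixtures):
    return {name: Chem.MolFromSmiles(f.smiles) for name, f in fixtures.items()}


@pytest.fixture(scope="session")
def small_cohorts():
    """200 molecules per cohort in 10 groups of 20; shared across tests."""
    return generate_cohorts(
        GeneratorConfig(n_per_cohort=200, group_size=20, seed=42, reference_set_size=25)
    )


@pytest.fixture(scope="session")
def default_cohorts():
    """The study conditions: 5000 per cohort, 10 chronological groups of 500."""
    return generate_cohorts(GeneratorConfig())
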