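import pytest

from ligsearch.chem import MoleculeGraph
from ligsearch.fixtures import (ComplexSpec, FixtureSpec, PlantedInteraction,
                                make_complex, make_study)
from ligsearch.formats_io import read_pdb
from ligsearch.interactions import ScoringScheme


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def study():
    """Synthetic study with the query's own complex plus three homologs."""
    return make_study(FixtureSpec(seed=1, include_self=True))


@pytest.fixture(scope="session")
def planted_complex():
    """A 30-residue complex with 2 planted hydrogen bonds and 1 contact."""
    spec = ComplexSpec(seed=7, n_residues=30, interactions=[
        PlantedInteraction(5, "hbond"), PlantedInteraction(12, "hbond"),
        PlantedInteraction(20, "contact")])
    text, truth = make_complex(spec)
    return read_pdb(text, structure_id=spec.structure_id), truth


@pytest.fixture(scope="session")
def benzene():
    return MoleculeGraph.from_smiles("c1ccccc1", name="benzene")
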