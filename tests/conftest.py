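import numpy as np
import pytest

from mpbind.fixtures import FixtureSpec, PlantedPartner, build_backbone, make_complex
from mpbind.registry import load_registry
from mpbind.structure_io import Chain, compute_virtual_atoms


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def _fresh_helix_chain(n=20, geometry="ideal_helix", seed=0):
    rng = np.random.default_rng(seed)
    residues = build_backbone(n, geometry, rng)
    for r in residues:
        compute_virtual_atoms(r)
    return Chain(chain_id="A", residues=residues)


@pytest.fixture()
def helix_chain():
    return _fresh_helix_chain()


@pytest.fixture(scope="session")
def helix_chain_session():
    return _fresh_helix_chain()


@pytest.fixture(scope="session")
def planted_complex(registry):
    """Two protein chains + one partner of each non-protein category."""
    spec = FixtureSpec(
        seed=7, n_chains=2, n_residues=40,
        partners=(
            PlantedPartner("ion", "ZN", anchor=5, distance=4.0),
            PlantedPartner("ligand", "FAD", anchor=20, distance=3.5),
            PlantedPartner("nucleotide", "DA", anchor=30, distance=4.5),
            PlantedPartner("lipid", "CLR", anchor=12, distance=4.8, target_chain=1),
            PlantedPartner("amino_acid", "GLY", anchor=35, distance=4.0),
        ),
    )
    return make_complex(spec, registry=registry)


@pytest.fixture(scope="session")
def featurized_graph(helix_chain_session):
    from mpbind.graph_features import featurize_chain

    return featurize_chain(helix_chain_session)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_chain(chain, rot, trans):
    """Rigidly transformed deep copy of a chain."""
    from mpbind.structure_io import Atom, Residue

    new_residues = []
    for res in chain.residues:
        atoms = [Atom(a.name, a.element, rot @ a.coords + trans, a.altloc)
                 for a in res.atoms]
        rr = Residue(res.comp_id, res.one_letter, res.author_number, res.index,
                     atoms=atoms)
        compute_virtual_atoms(rr)
        new_residues.append(rr)
    return Chain(chain_id=chain.chain_id, residues=new_residues)
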