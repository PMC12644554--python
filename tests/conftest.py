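import pytest

from abparse.config import Config
from abparse.fixtures import (
    pairing_showcase_large,
    pairing_showcase_small,
    write_fixture,
)
from abparse.structure_io import ChainStructure, Residue, parse_entry


@pytest.fixture
def config():
    return Config()


@pytest.fixture(scope="session")
def showcase_small(tmp_path_factory):
    """Two-Fab complex with the published-style interface-count table."""
    out = tmp_path_factory.mktemp("fx_small")
    cif, fasta, truth = write_fixture(pairing_showcase_small(), out)
    return cif, fasta, truth


@pytest.fixture(scope="session")
def showcase_large(tmp_path_factory):
    """Four-Fab complex with swapped-pairing decoy contacts."""
    out = tmp_path_factory.mktemp("fx_large")
    cif, fasta, truth = write_fixture(pairing_showcase_large(), out)
    return cif, fasta, truth


@pytest.fixture(scope="session")
def showcase_small_chains(showcase_small):
    cif, fasta, _ = showcase_small
    _, models, _ = parse_entry(cif, fasta)
    return {c.chain_id: c for c in models[1]}


@pytest.fixture(scope="session")
def showcase_large_chains(showcase_large):
    cif, fasta, _ = showcase_large
    _, models, _ = parse_entry(cif, fasta)
    return {c.chain_id: c for c in models[1]}


def make_point_chain(points, chain_id="X", model_id=1, names=None):
    """Bare ChainStructure from a list of per-residue heavy-atom coordinate
    lists: points[i] is a list of (x, y, z) for residue i+1."""
    residues = []
    for i, atom_coords in enumerate(points, start=1):
        atoms = []
        for j, (x, y, z) in enumerate(atom_coords):
            name = "CA" if j == 0 else f"CB{j}"
            atoms.append((name, float(x), float(y), float(z)))
        residues.append(
            Residue(name="ALA", seq_index=i, auth_number=i, insertion_code="", heavy_atoms=atoms)
        )
    cs = ChainStructure(
        chain_id=chain_id, model_id=model_id, entity_id="", residues=residues
    )
    cs.pdb_seq = "A" * len(residues)
    cs.filled_seq = cs.pdb_seq
    return cs


@pytest.fixture
def point_chain_factory():
    return make_point_chain


def random_cloud_chain(rng, chain_id, n_res, atoms_per_res=3, scale=20.0, model_id=1):
    pts = []
    for _ in range(n_res):
        base = rng.uniform(-scale, scale, size=3)
        pts.append([tuple(base + rng.uniform(-1.5, 1.5, size=3)) for _ in range(atoms_per_res)])
    return make_point_chain(pts, chain_id=chain_id, model_id=model_id)


@pytest.fixture
def random_cloud_factory():
    return random_cloud_chain
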