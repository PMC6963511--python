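import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from terpentox.structures import Molecule3D, MoleculeRecord, embed_conformer, load_study_compounds


def mol3d_from_atoms(symbols, coords, rec_id="toy"):
    """Build a Molecule3D from bare atoms and coordinates (no bonds); enough
    for the geometric and surface descriptors."""
    rw = Chem.RWMol()
    for s in symbols:
        a = Chem.Atom(s)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.AddConformer(conf)
    rec = MoleculeRecord(id=rec_id, name=rec_id, smiles="C")
    return Molecule3D(record=rec, mol=mol, energy=0.0, seed=0)


def mol3d_from_smiles(smiles, seed=42, n_conf=5, rec_id=None):
    rec = MoleculeRecord(id=rec_id or smiles, name=rec_id or smiles, smiles=smiles)
    return embed_conformer(rec, n_conf=n_conf, seed=seed)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def study_records():
    return load_study_compounds()


@pytest.fixture(scope="session")
def methane():
    return mol3d_from_smiles("C", rec_id="methane")


@pytest.fixture(scope="session")
def geraniol_3d(study_records):
    rec = next(r for r in study_records if r.id == "geraniol")
    return embed_conformer(rec, n_conf=5, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
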