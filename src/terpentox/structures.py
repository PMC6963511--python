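"""Chemical structure handling: input parsing, 3D embedding, axis alignment.

Structures enter as SMILES tables or SDF, are embedded with distance
geometry (ETKDG) and relaxed with a classical force field (MMFF94, falling
back to UFF where MMFF parameters are missing), and can be canonically
oriented along the principal axes of inertia for the geometry-dependent
descriptors (shadow areas).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

COMPOUND_CLASSES = ("monoterpenoid", "sesquiterpenoid", "norisoprenoid", "other")

DEFAULT_N_CONF = 20
DEFAULT_SEED = 42


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound of a study set: identity plus its chemical graph."""

    id: str
    name: str
    smiles: str
    cls: str = "other"

    def __post_init__(self) -> None:
        if self.cls not in COMPOUND_CLASSES:
            raise ValueError(
                f"unknown compound class {self.cls!r} for {self.id!r}; "
                f"expected one of {COMPOUND_CLASSES}"
            )

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"record {self.id!r}: unparsable SMILES {self.smiles!r}")
        return mol


@dataclass
class Molecule3D:
    """A single optimized conformer with explicit hydrogens.

    ``mol`` carries exactly one RDKit conformer; ``energy`` is the
    force-field energy of that conformer (kcal/mol-scale, arbitrary zero)
    and ``seed`` the embedding seed that produced it.
    """

    record: MoleculeRecord
    mol: Chem.Mol
    energy: float
    seed: int
    field_name: str = "MMFF94"

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def symbols(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.GetMass() for a in self.mol.GetAtoms()])

    @property
    def atoms(self) -> list[tuple[str, int, tuple[float, float, float]]]:
        xyz = self.coords
        return [
            (a.GetSymbol(), a.GetFormalCharge(), tuple(xyz[i]))
            for i, a in enumerate(self.mol.GetAtoms())
        ]

    @property
    def bonds(self) -> list[tuple[int, int, object]]:
        out = []
        for b in self.mol.GetBonds():
            if b.GetIsAromatic():
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    def with_coords(self, xyz: np.ndarray) -> "Molecule3D":
        """Copy with replaced conformer coordinates."""
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        for i, p in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, p.tolist())
        return replace(self, mol=mol)


def _records_from_rows(rows: Iterable[dict], source: str) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows, start=2):  # header is line 1
        rid = (row.get("id") or "").strip()
        smiles = (row.get("smiles") or "").strip()
        if not rid or not smiles:
            raise ValueError(f"{source}, line {lineno}: missing id or smiles")
        if rid in seen:
            raise ValueError(f"{source}, line {lineno}: duplicate id {rid!r}")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(
                f"{source}, line {lineno}: invalid SMILES {smiles!r} (id {rid!r})"
            )
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValueError(
                f"{source}, line {lineno}: SMILES {smiles!r} is not a single "
                f"connected molecule"
            )
        cls = (row.get("class") or "other").strip() or "other"
        records.append(
            MoleculeRecord(id=rid, name=(row.get("name") or rid).strip(), smiles=smiles, cls=cls)
        )
        seen.add(rid)
    return records


def read_structures(path: str | Path, format: str = "smiles_table") -> list[MoleculeRecord]:
    """Read a compound set from a SMILES CSV (columns id,name,smiles,class) or SDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles_table":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: expected a CSV header with a 'smiles' column")
            return _records_from_rows(reader, str(path))
    if format == "sdf":
        records = []
        seen: set[str] = set()
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path}: unparsable record #{i + 1}")
            rid = mol.GetProp("id") if mol.HasProp("id") else (
                mol.GetProp("_Name") if mol.GetProp("_Name") else f"mol{i + 1}"
            )
            if rid in seen:
                raise ValueError(f"{path}: duplicate id {rid!r} at record #{i + 1}")
            seen.add(rid)
            cls = mol.GetProp("class") if mol.HasProp("class") else "other"
            records.append(
                MoleculeRecord(
                    id=rid,
                    name=mol.GetProp("name") if mol.HasProp("name") else rid,
                    smiles=Chem.MolToSmiles(mol),
                    cls=cls,
                )
            )
        return records
    raise ValueError(f"unsupported format {format!r}; use 'smiles_table' or 'sdf'")


def write_structures(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write a SMILES table readable by :func:`read_structures`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "smiles", "class"])
        for rec in records:
            writer.writerow([rec.id, rec.name, rec.smiles, rec.cls])


def load_study_compounds() -> list[MoleculeRecord]:
    """The packaged 27-terpenoid study set (16/8/3 by class), curated SMILES."""
    ref = resources.files("terpentox").joinpath("data/compounds.csv")
    with resources.as_file(ref) as path:
        return read_structures(path, "smiles_table")


def embed_conformer(
    rec: MoleculeRecord,
    n_conf: int = DEFAULT_N_CONF,
    seed: int = DEFAULT_SEED,
) -> Molecule3D:
    """Embed ``n_conf`` distance-geometry conformers, relax each with MMFF94
    (UFF fallback), and return the lowest-energy one.

    Deterministic for a fixed ``(rec, n_conf, seed)``.
    """
    if n_conf < 1:
        raise ValueError("n_conf must be >= 1")
    mol = Chem.AddHs(rec.to_mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) if int(seed) > 0 else 1
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conf, params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conf, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {rec.id!r}")

    field_name = "MMFF94"
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        field_name = "UFF"
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    energies = np.array([e for _converged, e in results], dtype=float)
    best = int(np.argmin(energies))

    keep = Chem.Mol(mol, confId=int(conf_ids[best]))
    # Chem.Mol(mol, confId=...) keeps only the requested conformer
    keep.GetConformer().SetId(0)
    return Molecule3D(
        record=rec,
        mol=keep,
        energy=float(energies[best]),
        seed=int(seed),
        field_name=field_name,
    )


def optimized_energies(rec: MoleculeRecord, n_conf: int, seed: int) -> np.ndarray:
    """Force-field energies of all ``n_conf`` optimized conformers (test oracle
    support for the lowest-energy selection contract)."""
    mol = Chem.AddHs(rec.to_mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) if int(seed) > 0 else 1
    AllChem.EmbedMultipleConfs(mol, numConfs=n_conf, params=params)
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    return np.array([e for _c, e in results], dtype=float)


def inertia_tensor(xyz: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Moment-of-inertia tensor about the center of mass."""
    xyz = np.asarray(xyz, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d = xyz - com
    r2 = (d * d).sum(axis=1)
    eye = np.eye(3)
    return (m[:, None, None] * (r2[:, None, None] * eye - d[:, :, None] * d[:, None, :])).sum(axis=0)


def principal_axis_align(mol: Molecule3D) -> Molecule3D:
    """Center at the center of mass and rotate onto the principal axes of
    inertia, eigenvalues ascending on X, Y, Z.

    Sign convention: on each axis, the atom with the largest absolute
    coordinate ends up with a positive sign (ties leave the axis as is),
    which makes the orientation deterministic and the operation idempotent.
    """
    xyz = mol.coords
    if xyz.shape[0] < 1:
        raise ValueError("empty molecule")
    m = mol.masses
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    centered = xyz - com
    inertia = inertia_tensor(xyz, m)
    evals, evecs = np.linalg.eigh(inertia)  # ascending
    aligned = centered @ evecs
    for k in range(3):
        col = aligned[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            aligned[:, k] = -col
    return mol.with_coords(aligned)


def is_principal_axis_aligned(mol: Molecule3D, tol: float = 1e-6) -> bool:
    """True when the center of mass sits at the origin and the inertia tensor
    is diagonal with ascending eigenvalues."""
    xyz = mol.coords
    m = mol.masses
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    scale = max(1.0, float(np.abs(xyz).max()))
    if np.abs(com).max() > tol * scale:
        return False
    inertia = inertia_tensor(xyz, m)
    off = inertia - np.diag(np.diag(inertia))
    iscale = max(1.0, float(np.abs(inertia).max()))
    diag = np.diag(inertia)
    return bool(np.abs(off).max() <= 1e-6 * iscale and diag[0] <= diag[1] + 1e-9 * iscale
                and diag[1] <= diag[2] + 1e-9 * iscale)


def write_sdf(mols: Sequence[Molecule3D], path: str | Path) -> None:
    """Export conformers as SDF with energy and seed in the properties block."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            out = Chem.Mol(m.mol)
            out.SetProp("_Name", m.record.id)
            out.SetProp("id", m.record.id)
            out.SetProp("name", m.record.name)
            out.SetProp("class", m.record.cls)
            out.SetProp("energy", repr(m.energy))
            out.SetProp("seed", str(m.seed))
            out.SetProp("force_field", m.field_name)
            writer.write(out)
    finally:
        writer.close()
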