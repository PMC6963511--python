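"""CODESSA-style molecular descriptors.

Implements the descriptor families a classical heuristic-method QSAR draws
on: Zefirov/Sanderson electronegativity-equalization partial charges and the
charged-partial-surface-area (CPSA) set built on them, gyration-tensor
asphericity, projected shadow areas, Kier shape indices, Kier–Hall valence
connectivity, constitutional counts, and an additive log P. ``build_matrix``
assembles everything into a compounds x descriptors table with category
metadata, optionally merging externally supplied columns (e.g. semiempirical
orbital-population descriptors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from ._params import BONDI_RADII, DEFAULT_VDW_RADIUS, SANDERSON_EN, ZEFIROV_SCALE
from .structures import Molecule3D, is_principal_axis_aligned, principal_axis_align

CATEGORIES = (
    "constitutional",
    "topological",
    "geometrical",
    "electrostatic",
    "quantum_chemical",
    "physicochemical",
)


@dataclass(frozen=True)
class PartialCharges:
    """Per-atom partial charges in elementary-charge units."""

    charges: np.ndarray
    scheme: str = "zefirov_sanderson"

    def __len__(self) -> int:
        return len(self.charges)


@dataclass(frozen=True)
class SurfaceAreas:
    """Per-atom solvent-excluded exposed areas on the van der Waals surface."""

    per_atom: np.ndarray  # A^2, >= 0
    probe: float = 0.0

    @property
    def tmsa(self) -> float:
        """Total molecular surface area in A^2."""
        return float(self.per_atom.sum())


@dataclass(frozen=True)
class CPSASet:
    pnsa1: float  # A^2, area over negatively charged atoms
    ppsa1: float  # A^2, area over positively charged atoms
    wnsa1: float  # A^4/1000, PNSA1 * TMSA / 1000
    tmsa: float  # A^2


@dataclass(frozen=True)
class DescriptorMeta:
    name: str
    category: str
    source: str = "computed"  # or "external"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown descriptor category {self.category!r}")
        if self.source not in ("computed", "external"):
            raise ValueError(f"unknown descriptor source {self.source!r}")


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with per-column metadata; NaN marks missing."""

    values: pd.DataFrame
    meta: dict[str, DescriptorMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate compound ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate descriptor names")
        for name in self.values.columns:
            self.meta.setdefault(name, DescriptorMeta(name, "constitutional"))

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="id")

    def meta_records(self) -> list[dict]:
        return [
            {"name": m.name, "category": m.category, "source": m.source}
            for m in (self.meta[c] for c in self.values.columns)
        ]


# ---------------------------------------------------------------------------
# electrostatic: Zefirov/Sanderson charges and CPSA

def zefirov_charges(mol: Molecule3D | Chem.Mol, conserve: bool = True) -> PartialCharges:
    """Sanderson electronegativity-equalization (Zefirov) partial charges.

    The molecular electronegativity is the geometric mean of the atomic
    Sanderson values and each atom's charge follows the one-shot formula
    q_i = (chi_M - chi_i) / (2.08 sqrt(chi_i)). The raw formula does not
    conserve charge exactly; by default the small residual is redistributed
    uniformly so the charges sum to the net formal charge (``conserve=False``
    returns the raw values).
    """
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    missing = sorted({s for s in symbols if s not in SANDERSON_EN})
    if missing:
        raise ValueError(
            f"no Sanderson electronegativity parameter for element(s): {', '.join(missing)}"
        )
    chi = np.array([SANDERSON_EN[s] for s in symbols])
    chi_m = math.exp(float(np.log(chi).mean()))
    q = (chi_m - chi) / (ZEFIROV_SCALE * np.sqrt(chi))
    total = float(sum(a.GetFormalCharge() for a in rdmol.GetAtoms()))
    if conserve:
        q = q + (total - q.sum()) / len(q)
    return PartialCharges(charges=q)


def qc_max(charges: PartialCharges, mol: Molecule3D | Chem.Mol) -> float:
    """Maximum Zefirov partial charge over the carbon atoms."""
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    idx = [a.GetIdx() for a in rdmol.GetAtoms() if a.GetAtomicNum() == 6]
    if not idx:
        raise ValueError("no carbon atoms")
    return float(charges.charges[idx].max())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def vdw_radii(mol: Molecule3D | Chem.Mol) -> np.ndarray:
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    return np.array(
        [BONDI_RADII.get(a.GetSymbol(), DEFAULT_VDW_RADIUS) for a in rdmol.GetAtoms()]
    )


def vdw_surface(
    mol: Molecule3D,
    n_points: int = 960,
    probe: float = 0.0,
    radii: np.ndarray | None = None,
) -> SurfaceAreas:
    """Shrake–Rupley sphere sampling of the exposed van der Waals surface.

    With ``probe`` 0 (the default) this is the bare vdW surface used by the
    CPSA descriptors; a positive probe radius yields a solvent-accessible
    surface instead.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    xyz = mol.coords
    r = (radii if radii is not None else vdw_radii(mol)) + probe
    unit = _sphere_points(n_points)
    n = len(r)
    areas = np.empty(n)
    for i in range(n):
        pts = xyz[i] + r[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) >= r[i] + r[j]:
                continue
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > r[j] ** 2
        areas[i] = 4.0 * math.pi * r[i] ** 2 * exposed.mean()
    return SurfaceAreas(per_atom=areas, probe=probe)


def cpsa(charges: PartialCharges, surf: SurfaceAreas) -> CPSASet:
    """PNSA-1 / PPSA-1 / WNSA-1 from per-atom charges and exposed areas.

    Atoms with exactly zero charge count on the positive side; the partition
    identity PNSA1 + PPSA1 = TMSA holds by construction.
    """
    q = charges.charges
    a = surf.per_atom
    if len(q) != len(a):
        raise ValueError(f"length mismatch: {len(q)} charges vs {len(a)} areas")
    neg = q < 0
    pnsa1 = float(a[neg].sum())
    ppsa1 = float(a[~neg].sum())
    tmsa = surf.tmsa
    return CPSASet(pnsa1=pnsa1, ppsa1=ppsa1, wnsa1=pnsa1 * tmsa / 1000.0, tmsa=tmsa)


# ---------------------------------------------------------------------------
# geometrical: asphericity and shadow areas

def gyration_eigenvalues(
    xyz: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Ascending eigenvalues of the weighted gyration tensor."""
    xyz = np.asarray(xyz, dtype=float)
    w = np.ones(len(xyz)) if weights is None else np.asarray(weights, dtype=float)
    center = (w[:, None] * xyz).sum(axis=0) / w.sum()
    d = xyz - center
    S = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    return np.linalg.eigvalsh(S)


def asphericity_from_eigenvalues(lam: Sequence[float]) -> float:
    l1, l2, l3 = (float(v) for v in lam)
    s = l1 + l2 + l3
    if s <= 0:
        raise ValueError("all atoms coincident: gyration tensor is zero")
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    return num / (2.0 * s * s)


def asphericity(mol: Molecule3D, weights: str = "mass") -> float:
    """Asphericity Omega in [0, 1] from the gyration-tensor eigenvalues.

    Omega = [(l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2] / [2 (l1+l2+l3)^2], with the
    tensor mass-weighted by default (``weights='unit'`` treats all atoms
    equally). 0 marks a spherically symmetric arrangement, 1 a perfectly
    linear one; the value is invariant to rigid motion.
    """
    if weights not in ("mass", "unit"):
        raise ValueError("weights must be 'mass' or 'unit'")
    xyz = mol.coords
    if len(xyz) < 2 or np.allclose(xyz, xyz[0]):
        raise ValueError("need at least two non-coincident atoms")
    w = mol.masses if weights == "mass" else None
    return asphericity_from_eigenvalues(gyration_eigenvalues(xyz, w))


def shadow_areas(mol: Molecule3D, grid: float = 0.05) -> dict[str, float]:
    """Areas of the molecular shadows on the XY, XZ and YZ planes.

    The molecule must already be principal-axis aligned; each shadow is the
    rasterized union of the atomic van der Waals disks projected onto the
    plane, so the estimate converges to the true union-of-disks area as the
    grid spacing goes to 0.
    """
    if grid <= 0:
        raise ValueError("grid must be > 0")
    if not is_principal_axis_aligned(mol):
        raise ValueError("molecule is not principal-axis aligned; call principal_axis_align first")
    xyz = mol.coords
    radii = vdw_radii(mol)
    out = {}
    for label, (i, j) in (("S_XY", (0, 1)), ("S_XZ", (0, 2)), ("S_YZ", (1, 2))):
        out[label] = _union_disk_area(xyz[:, [i, j]], radii, grid)
    return out


def _union_disk_area(centers: np.ndarray, radii: np.ndarray, grid: float) -> float:
    lo = (centers - radii[:, None]).min(axis=0) - grid
    hi = (centers + radii[:, None]).max(axis=0) + grid
    xs = np.arange(lo[0], hi[0] + grid, grid)
    ys = np.arange(lo[1], hi[1] + grid, grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros(gx.shape, dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        covered |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    return float(covered.sum()) * grid * grid


# ---------------------------------------------------------------------------
# topological: Kier shape and Kier–Hall valence connectivity

def _heavy_graph(mol: Molecule3D | Chem.Mol) -> tuple[list[int], list[tuple[int, int]]]:
    """Hydrogen-suppressed graph as (node list, edge list over heavy atoms)."""
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    heavy = [a.GetIdx() for a in rdmol.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: k for k, idx in enumerate(heavy)}
    edges = []
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            edges.append((remap[i], remap[j]))
    return list(range(len(heavy))), edges


def count_paths(nodes: Sequence[int], edges: Sequence[tuple[int, int]], length: int) -> int:
    """Number of simple paths with ``length`` edges in an undirected graph,
    each path counted once (not per direction)."""
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    if length == 0:
        return len(nodes)
    count = 0

    def extend(path: list[int]) -> None:
        nonlocal count
        if len(path) == length + 1:
            count += 1
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for v in nodes:
        extend([v])
    return count // 2


def enumerate_paths(
    nodes: Sequence[int], edges: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, ...]]:
    """All simple paths with ``length`` edges, one orientation per path."""
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    if length == 0:
        return [(v,) for v in nodes]
    paths: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        if len(path) == length + 1:
            if path[0] < path[-1] or (path[0] == path[-1]):
                paths.append(tuple(path))
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for v in nodes:
        extend([v])
    return paths


def kier_kappa(mol: Molecule3D | Chem.Mol, order: int) -> float:
    """Kier shape index of the given order on the hydrogen-suppressed graph
    (no alpha modification).

    1k = A(A-1)^2 / P1^2, 2k = (A-1)(A-2)^2 / P2^2, and 3k uses
    (A-1)(A-3)^2 / P3^2 for odd A, (A-3)(A-2)^2 / P3^2 for even A, with A the
    heavy-atom count and P_m the number of m-edge paths.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    nodes, edges = _heavy_graph(mol)
    a = len(nodes)
    p = count_paths(nodes, edges, order)
    if p == 0:
        raise ValueError(f"no paths of length {order}: molecule too small for kappa{order}")
    if order == 1:
        return a * (a - 1) ** 2 / p**2
    if order == 2:
        return (a - 1) * (a - 2) ** 2 / p**2
    if a % 2 == 1:
        return (a - 1) * (a - 3) ** 2 / p**2
    return (a - 3) * (a - 2) ** 2 / p**2


def _delta_v(atom: Chem.Atom) -> float:
    """Kier–Hall valence delta: (Zv - h)/(Z - Zv - 1), reducing to Zv - h for
    second-row elements."""
    z = atom.GetAtomicNum()
    zv = Chem.GetPeriodicTable().GetNOuterElecs(z)
    h = atom.GetTotalNumHs(includeNeighbors=True)
    if z <= 10:
        dv = float(zv - h)
    else:
        dv = (zv - h) / (z - zv - 1)
    if dv <= 0:
        raise ValueError(
            f"non-positive valence delta for atom {atom.GetIdx()} ({atom.GetSymbol()})"
        )
    return dv


def kier_hall_chi_v(mol: Molecule3D | Chem.Mol, order: int) -> float:
    """Kier–Hall valence connectivity index of the given order.

    chi_v(m) sums (prod delta_v)^(-1/2) over all m-edge subpaths of the
    hydrogen-suppressed graph; an empty path set gives 0 by convention.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    heavy = [a for a in rdmol.GetAtoms() if a.GetAtomicNum() > 1]
    deltas = np.array([_delta_v(a) for a in heavy])
    nodes, edges = _heavy_graph(rdmol)
    total = 0.0
    for path in enumerate_paths(nodes, edges, order):
        total += 1.0 / math.sqrt(float(np.prod(deltas[list(path)])))
    return total


def kier_hall_chi(mol: Molecule3D | Chem.Mol, order: int) -> float:
    """Simple (non-valence) connectivity index: deltas are heavy-atom degrees."""
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    nodes, edges = _heavy_graph(mol)
    deg = np.zeros(len(nodes))
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    if (deg == 0).any() and order > 0:
        return 0.0
    total = 0.0
    for path in enumerate_paths(nodes, edges, order):
        d = deg[list(path)]
        if (d <= 0).any():
            continue
        total += 1.0 / math.sqrt(float(np.prod(d)))
    return total


# ---------------------------------------------------------------------------
# constitutional and physicochemical

def constitutional(mol: Molecule3D | Chem.Mol) -> dict[str, float]:
    """Atom/bond counts with explicit hydrogens, including the relative
    number of single bonds (aromatic bonds count as non-single)."""
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    if not any(a.GetAtomicNum() == 1 for a in rdmol.GetAtoms()) and any(
        a.GetTotalNumHs() > 0 for a in rdmol.GetAtoms()
    ):
        rdmol = Chem.AddHs(rdmol)
    n_single = n_double = n_triple = n_aromatic = 0
    for b in rdmol.GetBonds():
        if b.GetIsAromatic():
            n_aromatic += 1
        elif b.GetBondType() == Chem.BondType.SINGLE:
            n_single += 1
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            n_double += 1
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            n_triple += 1
    n_bonds = rdmol.GetNumBonds()
    atoms = rdmol.GetAtoms()
    counts = {
        "n_atoms": float(rdmol.GetNumAtoms()),
        "n_heavy": float(sum(1 for a in atoms if a.GetAtomicNum() > 1)),
        "n_C": float(sum(1 for a in atoms if a.GetAtomicNum() == 6)),
        "n_O": float(sum(1 for a in atoms if a.GetAtomicNum() == 8)),
        "n_H": float(sum(1 for a in atoms if a.GetAtomicNum() == 1)),
        "n_bonds": float(n_bonds),
        "n_single": float(n_single),
        "n_double": float(n_double),
        "n_triple": float(n_triple),
        "n_aromatic": float(n_aromatic),
        "n_rings": float(rdMolDescriptors.CalcNumRings(rdmol)),
        "mw": float(rdMolDescriptors.CalcExactMolWt(rdmol)),
        "relative_n_single_bonds": (n_single / n_bonds) if n_bonds else float("nan"),
    }
    return counts


def logp_additive(mol: Molecule3D | Chem.Mol) -> float:
    """Octanol/water log P as the Wildman–Crippen atomic-contribution sum.

    Implicit hydrogens are folded into their heavy atom's contribution, so
    the value is independent of hydrogen representation.
    """
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    contribs = rdMolDescriptors._CalcCrippenContribs(rdmol)
    return float(sum(c[0] for c in contribs))


def logp_contributions(mol: Molecule3D | Chem.Mol) -> list[float]:
    rdmol = mol.mol if isinstance(mol, Molecule3D) else mol
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(rdmol)]


# ---------------------------------------------------------------------------
# matrix assembly

_CATEGORY_OF = {
    "MW": "constitutional",
    "Natoms": "constitutional",
    "Nheavy": "constitutional",
    "Nrings": "constitutional",
    "NC": "constitutional",
    "NO": "constitutional",
    "RelSingleBonds": "constitutional",
    "Kappa1": "topological",
    "Kappa2": "topological",
    "Kappa3": "topological",
    "Chi0v": "topological",
    "Chi1v": "topological",
    "Chi2v": "topological",
    "Chi0": "topological",
    "Chi1": "topological",
    "Chi2": "topological",
    "Asphericity": "geometrical",
    "ShadowXY": "geometrical",
    "ShadowXZ": "geometrical",
    "ShadowYZ": "geometrical",
    "TMSA": "geometrical",
    "QCmax": "electrostatic",
    "Qmax": "electrostatic",
    "Qmin": "electrostatic",
    "PNSA1": "electrostatic",
    "PPSA1": "electrostatic",
    "WNSA1": "electrostatic",
    "LogP": "physicochemical",
}


def compute_descriptors(mol: Molecule3D, surface_points: int = 960) -> dict[str, float]:
    """All computed descriptors for one conformer, keyed by column name."""
    cons = constitutional(mol)
    charges = zefirov_charges(mol)
    surf = vdw_surface(mol, n_points=surface_points)
    cp = cpsa(charges, surf)
    aligned = principal_axis_align(mol)
    shadows = shadow_areas(aligned)

    def _try(fn, *a):
        try:
            return fn(*a)
        except ValueError:
            return float("nan")

    return {
        "MW": cons["mw"],
        "Natoms": cons["n_atoms"],
        "Nheavy": cons["n_heavy"],
        "Nrings": cons["n_rings"],
        "NC": cons["n_C"],
        "NO": cons["n_O"],
        "RelSingleBonds": cons["relative_n_single_bonds"],
        "Kappa1": _try(kier_kappa, mol, 1),
        "Kappa2": _try(kier_kappa, mol, 2),
        "Kappa3": _try(kier_kappa, mol, 3),
        "Chi0v": kier_hall_chi_v(mol, 0),
        "Chi1v": kier_hall_chi_v(mol, 1),
        "Chi2v": kier_hall_chi_v(mol, 2),
        "Chi0": kier_hall_chi(mol, 0),
        "Chi1": kier_hall_chi(mol, 1),
        "Chi2": kier_hall_chi(mol, 2),
        "Asphericity": asphericity(mol),
        "ShadowXY": shadows["S_XY"],
        "ShadowXZ": shadows["S_XZ"],
        "ShadowYZ": shadows["S_YZ"],
        "TMSA": cp.tmsa,
        "QCmax": _try(qc_max, charges, mol),
        "Qmax": float(charges.charges.max()),
        "Qmin": float(charges.charges.min()),
        "PNSA1": cp.pnsa1,
        "PPSA1": cp.ppsa1,
        "WNSA1": cp.wnsa1,
        "LogP": logp_additive(mol),
    }


def build_matrix(
    mols: Sequence[Molecule3D],
    include: Iterable[str] | None = None,
    external: pd.DataFrame | str | Path | None = None,
    external_category: str = "quantum_chemical",
    surface_points: int = 960,
) -> DescriptorMatrix:
    """Assemble the descriptor matrix for a set of conformers.

    ``include`` restricts to the given categories; ``external`` merges extra
    columns (CSV path or DataFrame keyed by compound id), flagged
    source='external' — compounds without a value get NaN, which the
    heuristic-method prescreen later eliminates.
    """
    ids = [m.record.id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in molecule list")
    rows = [compute_descriptors(m, surface_points=surface_points) for m in mols]
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    meta = {c: DescriptorMeta(c, _CATEGORY_OF[c]) for c in frame.columns}

    if include is not None:
        keep_cats = set(include)
        unknown = keep_cats - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        cols = [c for c in frame.columns if meta[c].category in keep_cats]
        frame = frame[cols]
        meta = {c: meta[c] for c in cols}

    if external is not None:
        if not isinstance(external, pd.DataFrame):
            external = pd.read_csv(external, index_col=0)
        external = external.apply(pd.to_numeric, errors="coerce")
        dup = set(external.columns) & set(frame.columns)
        if dup:
            raise ValueError(f"duplicate descriptor names: {sorted(dup)}")
        aligned_ext = external.reindex(frame.index)
        for c in aligned_ext.columns:
            meta[c] = DescriptorMeta(c, external_category, source="external")
        frame = pd.concat([frame, aligned_ext], axis=1)

    return DescriptorMatrix(values=frame, meta=meta)
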