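"""Geometric shape descriptors (asphericity, shadow areas) and topological
indices (Kier kappa, Kier–Hall chi), each checked against independent
closed-form or brute-force oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from terpentox.descriptors import (
    _heavy_graph,
    asphericity,
    asphericity_from_eigenvalues,
    count_paths,
    kier_hall_chi_v,
    kier_kappa,
    shadow_areas,
    vdw_radii,
)
from terpentox.structures import principal_axis_align

from conftest import mol3d_from_atoms, mol3d_from_smiles, random_rotation


class TestAsphericity:
    def test_linear_is_one(self):
        mol = mol3d_from_atoms(["C", "C", "C"], [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        assert asphericity(mol) == pytest.approx(1.0, abs=1e-12)

    def test_tetrahedron_is_zero(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        mol = mol3d_from_atoms(["C"] * 4, verts)
        assert asphericity(mol) == pytest.approx(0.0, abs=1e-12)

    def test_range_and_rigid_motion_invariance(self, rng):
        for _ in range(5):
            xyz = rng.normal(size=(8, 3)) * 3
            mol = mol3d_from_atoms(["C"] * 5 + ["O"] * 3, xyz)
            val = asphericity(mol)
            assert 0.0 <= val <= 1.0
            R = random_rotation(rng)
            moved = mol.with_coords(xyz @ R.T + rng.normal(size=3) * 10)
            assert asphericity(moved) == pytest.approx(val, rel=1e-6)

    def test_unit_weight_variant_differs_generically(self, geraniol_3d):
        assert asphericity(geraniol_3d, "mass") != pytest.approx(
            asphericity(geraniol_3d, "unit"), abs=1e-6
        )

    def test_coincident_atoms_error(self):
        mol = mol3d_from_atoms(["C", "C"], [[1, 2, 3], [1, 2, 3]])
        with pytest.raises(ValueError):
            asphericity(mol)

    def test_degenerate_eigenvalue_input(self):
        with pytest.raises(ValueError):
            asphericity_from_eigenvalues([0.0, 0.0, 0.0])


class TestShadowAreas:
    def test_single_atom_disk(self):
        # a single atom at the origin is trivially aligned
        mol = mol3d_from_atoms(["Ar"], [[0.0, 0.0, 0.0]])
        shadows = shadow_areas(mol, grid=0.05)
        exact = math.pi * 1.88**2
        for v in shadows.values():
            assert v == pytest.approx(exact, rel=0.01)

    def test_two_spheres_along_axis(self):
        r = 1.88
        mol = mol3d_from_atoms(["Ar", "Ar"], [[0, 0, -2 * r], [0, 0, 2 * r]])
        aligned = principal_axis_align(mol)
        shadows = shadow_areas(aligned, grid=0.04)
        # long axis lands on X after alignment: the YZ shadow is one disk,
        # the XY and XZ shadows two disjoint disks
        assert shadows["S_YZ"] == pytest.approx(math.pi * r**2, rel=0.02)
        assert shadows["S_XY"] == pytest.approx(2 * math.pi * r**2, rel=0.02)
        assert shadows["S_XZ"] == pytest.approx(2 * math.pi * r**2, rel=0.02)

    def test_overlapping_disks_lens_oracle(self):
        """Union of two equal disks versus the closed-form lens area."""
        r, d = 1.7, 1.0
        mol = mol3d_from_atoms(["C", "C"], [[-d / 2, 0, 0], [d / 2, 0, 0]])
        aligned = principal_axis_align(mol)
        shadows = shadow_areas(aligned, grid=0.02)
        lens = 2 * r**2 * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r**2 - d**2)
        union = 2 * math.pi * r**2 - lens
        assert shadows["S_XY"] == pytest.approx(union, rel=0.02)
        assert shadows["S_XZ"] == pytest.approx(union, rel=0.02)
        # along the bond axis the two disks coincide
        assert shadows["S_YZ"] == pytest.approx(math.pi * r**2, rel=0.02)

    def test_unaligned_input_rejected(self, geraniol_3d):
        with pytest.raises(ValueError, match="align"):
            shadow_areas(geraniol_3d.with_coords(geraniol_3d.coords + 7.0))

    def test_grid_validation(self, geraniol_3d):
        with pytest.raises(ValueError):
            shadow_areas(principal_axis_align(geraniol_3d), grid=0.0)


# --- brute-force graph oracles ------------------------------------------------

def _nx_graph(mol):
    nodes, edges = _heavy_graph(mol)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def _nx_path_count(g, length):
    """Count simple paths with `length` edges by exhaustive enumeration."""
    if length == 0:
        return g.number_of_nodes()
    seen = set()
    for u, v in itertools.permutations(g.nodes, 2):
        for path in nx.all_simple_paths(g, u, v, cutoff=length):
            if len(path) == length + 1:
                key = tuple(path) if path[0] < path[-1] else tuple(reversed(path))
                seen.add(key)
    return len(seen)


def _oracle_kappa(mol, order):
    g = _nx_graph(mol)
    a = g.number_of_nodes()
    p = _nx_path_count(g, order)
    if order == 1:
        return a * (a - 1) ** 2 / p**2
    if order == 2:
        return (a - 1) * (a - 2) ** 2 / p**2
    if a % 2 == 1:
        return (a - 1) * (a - 3) ** 2 / p**2
    return (a - 3) * (a - 2) ** 2 / p**2


ALKANE_SMILES = [
    "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CC(C)(C)C",
    "CCCCCC", "CC(C)CCC", "CCC(C)CC", "CC(C)(C)CC", "CC(C)C(C)C",
    "CCCCCCC", "CC(C)CCCC", "CCCCCCCC", "CC(C)(C)CCC",
    "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCCCCCC1",
    "CC1CCCC1", "CC1(C)CCC1", "C1CC2CC1C2",
]


class TestKierKappa:
    def test_pentane_kappa1(self):
        assert kier_kappa(Chem.MolFromSmiles("CCCCC"), 1) == pytest.approx(5.0)

    def test_cyclohexane_kappa1(self):
        assert kier_kappa(Chem.MolFromSmiles("C1CCCCC1"), 1) == pytest.approx(6 * 25 / 36)

    def test_hexane_kappa3_even_parity(self):
        assert kier_kappa(Chem.MolFromSmiles("CCCCCC"), 3) == pytest.approx(48 / 9)

    def test_too_small_molecule_errors(self):
        with pytest.raises(ValueError):
            kier_kappa(Chem.MolFromSmiles("CC"), 3)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_against_path_enumeration_oracle(self, order):
        """kappa agrees with an exhaustive networkx path enumeration on all
        skeletons with <= 8 heavy atoms."""
        for smiles in ALKANE_SMILES:
            mol = Chem.MolFromSmiles(smiles)
            g = _nx_graph(mol)
            if _nx_path_count(g, order) == 0:
                continue
            assert kier_kappa(mol, order) == pytest.approx(
                _oracle_kappa(mol, order), abs=1e-12
            ), smiles


class TestCountPaths:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_networkx_enumeration(self, order):
        for smiles in ALKANE_SMILES:
            mol = Chem.MolFromSmiles(smiles)
            nodes, edges = _heavy_graph(mol)
            g = _nx_graph(mol)
            assert count_paths(nodes, edges, order) == _nx_path_count(g, order), smiles


class TestChiV:
    def test_propane_order2(self):
        assert kier_hall_chi_v(Chem.MolFromSmiles("CCC"), 2) == pytest.approx(1 / math.sqrt(2))

    def test_isobutane_order2(self):
        assert kier_hall_chi_v(Chem.MolFromSmiles("CC(C)C"), 2) == pytest.approx(math.sqrt(3))

    def test_ethane_order2_empty_sum(self):
        assert kier_hall_chi_v(Chem.MolFromSmiles("CC"), 2) == 0.0

    def test_against_delta_oracle(self):
        """chi_v(2) recomputed by explicit path enumeration with hand deltas
        on heteroatom-bearing molecules."""
        for smiles in ["CCO", "CC(C)O", "CC=O", "CCOCC", "CC(C)=CCO"]:
            mol = Chem.MolFromSmiles(smiles)
            pt = Chem.GetPeriodicTable()
            heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
            deltas = []
            for a in heavy:
                zv = pt.GetNOuterElecs(a.GetAtomicNum())
                deltas.append(zv - a.GetTotalNumHs(includeNeighbors=True))
            g = _nx_graph(mol)
            total = 0.0
            seen = set()
            for u, v in itertools.permutations(g.nodes, 2):
                for path in nx.all_simple_paths(g, u, v, cutoff=2):
                    if len(path) == 3:
                        key = tuple(path) if path[0] < path[-1] else tuple(reversed(path))
                        if key not in seen:
                            seen.add(key)
                            total += 1 / math.sqrt(
                                deltas[path[0]] * deltas[path[1]] * deltas[path[2]]
                            )
            assert kier_hall_chi_v(mol, 2) == pytest.approx(total, abs=1e-12), smiles
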