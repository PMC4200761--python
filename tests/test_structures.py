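"""Structure/grid I/O, rotatable bonds, and conformer deduplication."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from patchscreen.structures import (
    AtomRecord,
    ConformerSet,
    MoleculeStructure,
    ScalarGrid3D,
    StructureFormatError,
    best_fit_rmsd,
    count_rotatable_bonds,
    filter_conformers,
    read_conformers,
    read_dx_grid,
    read_structure,
    rmsd_threshold,
    write_dx_grid,
    write_pqr,
    write_sdf,
)


def _mol(coords, elements=None, bonds=(), charges=None):
    coords = np.asarray(coords, dtype=float)
    elements = elements or ["C"] * len(coords)
    charges = charges if charges is not None else [0.0] * len(coords)
    atoms = [
        AtomRecord(i + 1, f"{e}{i+1}", e, c, q, 1.7 if e != "H" else 1.2)
        for i, (e, c, q) in enumerate(zip(elements, coords, charges))
    ]
    return MoleculeStructure(atoms, list(bonds), id="test")


class TestReaders:
    def test_pqr_fields_copied(self, tmp_path):
        p = tmp_path / "x.pqr"
        p.write_text("ATOM      1  C   MOL     1       1.000   2.000   3.000 -0.3000  1.7000\nEND\n")
        mol = read_structure(p)
        atom = mol.atoms[0]
        assert atom.charge == pytest.approx(-0.3)
        assert atom.radius == pytest.approx(1.7)
        assert np.allclose(atom.coords, [1, 2, 3])
        assert atom.is_heavy

    def test_pdb_single_atom(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00           C\nEND\n"
        )
        with pytest.warns(UserWarning):
            mol = read_structure(p)
        assert len(mol.atoms) == 1
        assert np.allclose(mol.atoms[0].coords, [11, 12, 13], atol=1e-3)

    def test_sdf_conformer_set_round_trip(self, tmp_path):
        base = _mol([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], ["C", "N", "O"], [(1, 2, 1), (2, 3, 1)])
        shifted = base.with_coords(base.coords + [0, 1, 0])
        cs = ConformerSet("LIG", [base, shifted])
        path = tmp_path / "lig.sdf"
        write_sdf(cs, path)
        back = read_conformers(path)
        assert len(back) == 2
        assert len(back.conformers[0].atoms) == len(back.conformers[1].atoms) == 3
        assert np.allclose(back.conformers[0].coords, base.coords, atol=1e-3)
        assert [a.element for a in back.conformers[0].atoms] == ["C", "N", "O"]

    def test_pqr_round_trip_preserves_coords(self, tmp_path):
        mol = _mol(np.array([[0.123, -4.567, 8.901], [1.0, 2.0, 3.0]]), charges=[0.5, -0.5])
        path = tmp_path / "m.pqr"
        write_pqr(mol, path)
        back = read_structure(path)
        assert np.allclose(back.coords, mol.coords, atol=1e-3)
        assert np.allclose(back.charges, mol.charges, atol=1e-4)

    def test_empty_structure_errors(self, tmp_path):
        p = tmp_path / "empty.pqr"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(StructureFormatError):
            read_structure(p)


class TestDxGrid:
    def test_tiny_grid_round_trip(self, tmp_path):
        grid = ScalarGrid3D([0, 0, 0], [0.5, 0.5, 0.5], np.ones((2, 2, 2)))
        path = tmp_path / "g.dx"
        write_dx_grid(grid, path)
        back = read_dx_grid(path)
        assert back.dims == (2, 2, 2)
        assert np.allclose(back.values, 1.0, atol=1e-6)
        assert np.allclose(back.origin, grid.origin)
        assert np.allclose(back.spacing, grid.spacing)

    def test_round_trip_identity_on_values(self, tmp_path):
        rng = np.random.default_rng(3)
        grid = ScalarGrid3D([-1, 0, 2], [0.4, 0.5, 0.6], rng.normal(size=(3, 4, 5)))
        path = tmp_path / "g.dx"
        write_dx_grid(grid, path)
        assert np.allclose(read_dx_grid(path).values, grid.values, atol=1e-6)

    def test_truncated_data_is_corruption_error(self, tmp_path):
        grid = ScalarGrid3D([0, 0, 0], [1, 1, 1], np.ones((2, 2, 2)))
        path = tmp_path / "g.dx"
        write_dx_grid(grid, path)
        lines = path.read_text().splitlines()
        # drop one data value (7 of 8 remain)
        data_line = next(i for i, l in enumerate(lines) if l.startswith("1.0"))
        lines[data_line] = " ".join(lines[data_line].split()[:-1])
        path.write_text("\n".join(lines))
        with pytest.raises(StructureFormatError, match="corrupt"):
            read_dx_grid(path)


class TestRotatableBonds:
    def test_ethane_like_no_rotatable(self):
        # two heavy atoms, both terminal: the C-C bond is not rotatable
        mol = _mol([[0, 0, 0], [1.5, 0, 0]], bonds=[(1, 2, 1)])
        assert count_rotatable_bonds(mol) == 0

    def test_n_butane_single_rotatable(self):
        # brute-force expectation: only the C2-C3 bond joins two non-terminal atoms
        coords = [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]]
        mol = _mol(coords, bonds=[(1, 2, 1), (2, 3, 1), (3, 4, 1)])
        assert count_rotatable_bonds(mol) == 1

    def test_benzene_ring_bonds_not_rotatable(self):
        theta = np.linspace(0, 2 * np.pi, 7)[:-1]
        coords = np.column_stack([1.4 * np.cos(theta), 1.4 * np.sin(theta), np.zeros(6)])
        bonds = [(i + 1, (i + 1) % 6 + 1, 1) for i in range(6)]
        mol = _mol(coords, bonds=bonds)
        assert count_rotatable_bonds(mol) == 0

    def test_no_bond_table_errors(self):
        with pytest.raises(ValueError, match="bond"):
            count_rotatable_bonds(_mol([[0, 0, 0], [1.5, 0, 0]]))


def _chain_conformers(n_atoms=12, n_conf=3, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    base = np.cumsum(rng.normal(scale=1.0, size=(n_atoms, 3)), axis=0)
    bonds = [(i, i + 1, 1) for i in range(1, n_atoms)]
    confs = []
    for k in range(n_conf):
        confs.append(_mol(base + rng.normal(scale=scale * k, size=base.shape), bonds=bonds))
    return ConformerSet("LIG", confs)


class TestConformerFilter:
    def test_identical_conformers_collapse(self):
        mol = _mol([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], bonds=[(1, 2, 1), (2, 3, 1)])
        cs = ConformerSet("LIG", [mol, mol.with_coords(mol.coords)])
        assert len(filter_conformers(cs)) == 1

    def test_cap_at_twenty(self):
        # 25 distinct random shapes (best-fit RMSD between any two >> cutoff)
        rng = np.random.default_rng(5)
        mols = []
        for k in range(25):
            coords = rng.normal(scale=4, size=(6, 3))
            mols.append(_mol(coords, bonds=[(i, i + 1, 1) for i in range(1, 6)]))
        assert len(filter_conformers(ConformerSet("L", mols))) == 20

    def test_threshold_depends_on_flexibility(self):
        # 9 heavy atoms in a chain: 6 rotatable bonds -> 0.8 Å cutoff
        n = 9
        base = np.column_stack([np.arange(n) * 1.5, np.zeros(n), np.zeros(n)])
        bonds = [(i, i + 1, 1) for i in range(1, n)]
        a = _mol(base, bonds=bonds)
        assert count_rotatable_bonds(a) == 6
        assert rmsd_threshold(6) == 0.8
        # perturb to a best-fit RMSD of ~0.9 Å (> 0.8): both kept
        rng = np.random.default_rng(2)
        delta = rng.normal(size=base.shape)
        delta -= delta.mean(axis=0)
        for _ in range(4):  # best-fit RMSD is not linear in the perturbation scale
            delta *= 0.9 / best_fit_rmsd(base + delta, base)
        b = _mol(base + delta, bonds=bonds)
        assert 0.85 < best_fit_rmsd(a.coords, b.coords) < 0.95
        assert len(filter_conformers(ConformerSet("L", [a, b]))) == 2
        # shrink below the cutoff: the near-duplicate is dropped
        c = _mol(base + delta * 0.5, bonds=bonds)
        assert len(filter_conformers(ConformerSet("L", [a, c]))) == 1

    def test_filter_is_idempotent(self):
        cs = _chain_conformers(n_conf=6, scale=0.4)
        once = filter_conformers(cs)
        twice = filter_conformers(once)
        assert len(once) == len(twice)
        for x, y in zip(once.conformers, twice.conformers):
            assert np.allclose(x.coords, y.coords)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmsd_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=a.shape)
        rot = Rotation.random(random_state=seed).as_matrix()
        b_moved = b @ rot.T + rng.normal(size=3)
        assert best_fit_rmsd(a, b) == pytest.approx(best_fit_rmsd(a, b_moved), abs=1e-9)
        # oracle: brute-force Kabsch via scipy on centered coordinates
        a0 = a - a.mean(axis=0)
        b0 = b_moved - b_moved.mean(axis=0)
        rot_fit, rssd = Rotation.align_vectors(a0, b0)
        assert best_fit_rmsd(a, b_moved) == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-12)
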