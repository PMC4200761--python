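"""Molecular structure and scalar-grid I/O, conformer bookkeeping.

Readers accept PDB (via gemmi), PQR (whitespace dialect), MOL2 and SDF
(via RDKit).  Multi-record SDF files are interpreted as conformer sets of
a single ligand.  Scalar grids use the OpenDX "gridpositions counts"
format with z-fastest value ordering, the convention of Poisson-Boltzmann
solvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "MoleculeStructure",
    "ConformerSet",
    "ScalarGrid3D",
    "ELEMENT_RADII",
    "ATOMIC_MASSES",
    "read_structure",
    "read_conformers",
    "write_pqr",
    "write_sdf",
    "read_dx_grid",
    "write_dx_grid",
    "count_rotatable_bonds",
    "best_fit_rmsd",
    "rmsd_threshold",
    "filter_conformers",
]

#: Fallback van der Waals / PB radii (Å) for inputs without a radius column.
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2}
DEFAULT_RADIUS = 1.7

#: Standard atomic masses (u) for center-of-mass computations.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}
DEFAULT_MASS = 12.011


class StructureFormatError(ValueError):
    """Raised when a structure or grid file cannot be parsed."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), DEFAULT_MASS)


@dataclass
class MoleculeStructure:
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        serials = {a.serial for a in self.atoms}
        for s1, s2, _order in self.bonds:
            if s1 not in serials or s2 not in serials:
                raise ValueError(f"bond ({s1},{s2}) references missing atom serial")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms])

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def with_coords(self, coords: np.ndarray, new_id: str | None = None) -> "MoleculeStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.serial, a.name, a.element, c, a.charge, a.radius)
            for a, c in zip(self.atoms, coords)
        ]
        return MoleculeStructure(atoms, list(self.bonds), new_id if new_id is not None else self.id)


@dataclass
class ConformerSet:
    ligand_id: str
    conformers: list[MoleculeStructure]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("conformer set must contain at least one conformer")
        ref = self.conformers[0]
        for c in self.conformers[1:]:
            if len(c.atoms) != len(ref.atoms):
                raise ValueError("conformers differ in atom count")
            for a, b in zip(c.atoms, ref.atoms):
                if a.element.upper() != b.element.upper():
                    raise ValueError("conformers differ in element ordering")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class ScalarGrid3D:
    """Regular scalar field: values[i, j, k] at origin + (i,j,k) * spacing."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.dims[d]) for d in range(3)
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"pdb", "ent"}:
        return "pdb"
    if suffix in {"pqr", "mol2", "sdf", "sd"}:
        return "sdf" if suffix == "sd" else suffix
    raise StructureFormatError(f"cannot infer structure format from {path!r}")


def read_structure(path: str | Path, format: str | None = None) -> MoleculeStructure:
    """Read one molecule from a PDB, PQR, MOL2 or SDF file.

    PQR populates partial charges and radii; plain PDB falls back to
    element-default radii and zero charge (with a warning) so that
    shape-only workflows run without a PQR file.
    """
    fmt = format or _infer_format(path)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pqr":
        return _read_pqr(path)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt in {"mol2", "sdf"}:
        mols = _read_rdkit(path, fmt)
        return mols[0]
    raise StructureFormatError(f"unsupported format {fmt!r}")


def read_conformers(path: str | Path, ligand_id: str | None = None) -> ConformerSet:
    """Read a multi-record SDF (or MOL2) file as a conformer set."""
    fmt = _infer_format(path)
    if fmt not in {"sdf", "mol2"}:
        raise StructureFormatError("conformer sets are read from SDF or MOL2 files")
    mols = _read_rdkit(Path(path), fmt)
    lid = ligand_id or mols[0].id or Path(path).stem
    return ConformerSet(lid, mols)


def _read_pqr(path: Path) -> MoleculeStructure:
    atoms = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        tok = line.split()
        try:
            # recordName serial atomName resName [chain] resNum x y z charge radius
            serial = int(tok[1])
            name = tok[2]
            x, y, z, charge, radius = (float(v) for v in tok[-5:])
        except (ValueError, IndexError) as exc:
            raise StructureFormatError(f"{path}:{lineno}: malformed PQR record") from exc
        element = _element_from_name(name)
        atoms.append(AtomRecord(serial, name, element, (x, y, z), charge, radius))
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms found")
    return MoleculeStructure(atoms, id=path.stem)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR"}:
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "C"


def _read_pdb(path: Path) -> MoleculeStructure:
    import gemmi

    st = gemmi.read_structure(str(path))
    atoms = []
    serial = 0
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    serial += 1
                    element = atom.element.name or _element_from_name(atom.name)
                    radius = ELEMENT_RADII.get(element.upper()[:1], DEFAULT_RADIUS)
                    if element.upper() in ELEMENT_RADII:
                        radius = ELEMENT_RADII[element.upper()]
                    atoms.append(
                        AtomRecord(
                            serial,
                            atom.name,
                            element,
                            (atom.pos.x, atom.pos.y, atom.pos.z),
                            0.0,
                            radius,
                        )
                    )
        break  # first model only
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms found")
    warnings.warn(
        f"{path.name}: PDB carries no charges/radii; using element-default radii and zero charge",
        stacklevel=2,
    )
    return MoleculeStructure(atoms, id=path.stem)


def _read_rdkit(path: Path, fmt: str) -> list[MoleculeStructure]:
    from rdkit import Chem

    if fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
        rdkit_mols = [mol] if mol is not None else []
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        rdkit_mols = [m for m in supplier if m is not None]
    if not rdkit_mols:
        raise StructureFormatError(f"{path}: no parsable molecules")
    out = []
    for idx, rdmol in enumerate(rdkit_mols):
        conf = rdmol.GetConformer()
        atoms = []
        for atom in rdmol.GetAtoms():
            i = atom.GetIdx()
            pos = conf.GetAtomPosition(i)
            element = atom.GetSymbol()
            radius = ELEMENT_RADII.get(element.upper(), DEFAULT_RADIUS)
            charge = float(atom.GetDoubleProp("_GasteigerCharge")) if atom.HasProp("_GasteigerCharge") else 0.0
            atoms.append(AtomRecord(i + 1, element + str(i + 1), element, (pos.x, pos.y, pos.z), charge, radius))
        bonds = [
            (b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1, int(b.GetBondTypeAsDouble()))
            for b in rdmol.GetBonds()
        ]
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else path.stem
        out.append(MoleculeStructure(atoms, bonds, id=f"{name}" if len(rdkit_mols) == 1 else f"{name}_{idx}"))
    return out


def write_pqr(mol: MoleculeStructure, path: str | Path) -> None:
    lines = []
    for a in mol.atoms:
        lines.append(
            "ATOM  %5d %-4s %-3s %5d    %8.3f %8.3f %8.3f %8.4f %7.4f"
            % (a.serial, a.name[:4], "MOL", 1, a.coords[0], a.coords[1], a.coords[2], a.charge, a.radius)
        )
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_sdf(conformers: ConformerSet | MoleculeStructure, path: str | Path) -> None:
    """Write a molecule or conformer set as a (multi-record) V2000 SDF."""
    if isinstance(conformers, MoleculeStructure):
        conformers = ConformerSet(conformers.id or "MOL", [conformers])
    blocks = []
    for mol in conformers.conformers:
        n_atoms, n_bonds = len(mol.atoms), len(mol.bonds)
        lines = [mol.id or conformers.ligand_id, "  patchscreen", ""]
        lines.append("%3d%3d  0  0  0  0  0  0  0  0999 V2000" % (n_atoms, n_bonds))
        for a in mol.atoms:
            lines.append(
                "%10.4f%10.4f%10.4f %-3s 0  0  0  0  0  0  0  0  0  0  0  0"
                % (a.coords[0], a.coords[1], a.coords[2], a.element)
            )
        serial_to_index = {a.serial: i + 1 for i, a in enumerate(mol.atoms)}
        for s1, s2, order in mol.bonds:
            lines.append("%3d%3d%3d  0" % (serial_to_index[s1], serial_to_index[s2], max(order, 1)))
        lines.append("M  END")
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def read_dx_grid(path: str | Path) -> ScalarGrid3D:
    """Read an OpenDX 'gridpositions counts' scalar grid (z-fastest order)."""
    path = Path(path)
    dims = origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    expected = None
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("object 1"):
            tok = s.split()
            dims = tuple(int(v) for v in tok[-3:])
            expected = dims[0] * dims[1] * dims[2]
        elif s.startswith("origin"):
            origin = np.array([float(v) for v in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append(np.array([float(v) for v in s.split()[1:4]]))
        elif s.startswith(("object", "attribute", "component")):
            continue
        else:
            values.extend(float(v) for v in s.split())
    if dims is None or origin is None or len(deltas) != 3:
        raise StructureFormatError(f"{path}: missing DX header records")
    if expected != len(values):
        raise StructureFormatError(
            f"{path}: corrupt DX data, expected {expected} values, found {len(values)}"
        )
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    grid = np.array(values).reshape(dims)  # z fastest = last axis in C order
    return ScalarGrid3D(origin, spacing, grid)


def write_dx_grid(grid: ScalarGrid3D, path: str | Path, comment: str = "scalar grid") -> None:
    nx_, ny_, nz_ = grid.dims
    lines = [f"# {comment}"]
    lines.append(f"object 1 class gridpositions counts {nx_} {ny_} {nz_}")
    lines.append("origin %.6e %.6e %.6e" % tuple(grid.origin))
    lines.append("delta %.6e 0.000000e+00 0.000000e+00" % grid.spacing[0])
    lines.append("delta 0.000000e+00 %.6e 0.000000e+00" % grid.spacing[1])
    lines.append("delta 0.000000e+00 0.000000e+00 %.6e" % grid.spacing[2])
    lines.append(f"object 2 class gridconnections counts {nx_} {ny_} {nz_}")
    n = nx_ * ny_ * nz_
    lines.append(f"object 3 class array type double rank 0 items {n} data follows")
    flat = grid.values.reshape(-1)
    for i in range(0, n, 3):
        lines.append(" ".join("%.6e" % v for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Conformer bookkeeping


def count_rotatable_bonds(mol: MoleculeStructure) -> int:
    """Count single, acyclic bonds between two non-terminal heavy atoms."""
    if not mol.bonds:
        raise ValueError(
            "no bond table: rotatable-bond counting needs a bond-aware format (SDF/MOL2)"
        )
    heavy = {a.serial for a in mol.atoms if a.is_heavy}
    g = nx.Graph()
    g.add_nodes_from(heavy)
    orders = {}
    for s1, s2, order in mol.bonds:
        if s1 in heavy and s2 in heavy:
            g.add_edge(s1, s2)
            orders[frozenset((s1, s2))] = order
    bridges = set(frozenset(e) for e in nx.bridges(g)) if g.number_of_edges() else set()
    count = 0
    for edge, order in orders.items():
        if order != 1 or edge not in bridges:
            continue  # multiple-order or ring bond
        s1, s2 = tuple(edge)
        if g.degree[s1] >= 2 and g.degree[s2] >= 2:
            count += 1
    return count


def best_fit_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Heavy-atom RMSD after optimal (Kabsch) superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have identical shapes")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def rmsd_threshold(n_rotatable: int) -> float:
    """Dedup RMSD cutoff as a function of ligand flexibility."""
    if n_rotatable <= 5:
        return 0.5
    if n_rotatable <= 10:
        return 0.8
    return 1.0


def filter_conformers(conformer_set: ConformerSet, max_keep: int = 20) -> ConformerSet:
    """Greedy keep-first deduplication of a conformer set.

    A conformer is dropped when its best-fit heavy-atom RMSD to any already
    kept conformer falls below a flexibility-dependent cutoff (0.5 Å for
    0-5 rotatable bonds, 0.8 Å for 6-10, 1.0 Å above); at most ``max_keep``
    conformers are retained.
    """
    first = conformer_set.conformers[0]
    n_rot = count_rotatable_bonds(first) if first.bonds else 0
    cutoff = rmsd_threshold(n_rot)
    kept: list[MoleculeStructure] = []
    kept_coords: list[np.ndarray] = []
    for conf in conformer_set.conformers:
        coords = conf.coords[conf.heavy_mask]
        if all(best_fit_rmsd(coords, prev) >= cutoff for prev in kept_coords):
            kept.append(conf)
            kept_coords.append(coords)
        if len(kept) >= max_keep:
            break
    return ConformerSet(conformer_set.ligand_id, kept)
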