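"""Deterministic toy molecules and complementary pocket-ligand fixtures.

These generators provide a download-free test surface for the whole
pipeline.  The "ligand" is a connected random-walk blob of pseudo-atoms
with varied radii (a rugged, drug-sized surface); the "protein" is a cast
of the ligand: a double layer of pseudo-atoms placed along the outward
normals of the ligand surface, leaving a narrow gap, with the top of the
cast removed so the cavity is open like a real binding cleft.  Because
the wall is molded onto the ligand, facing patches are genuinely
complementary — locally mirrored geometry and, under the dipolar charge
pattern, a positive wall against a negative ligand.

Screening sets pair jittered copies of the cavity-filling ligand
(actives) with reshuffled-geometry blobs of the same composition
(decoys), emulating the structure of physically similar but topologically
different decoy libraries at toy scale.

Every generator is a pure function of its spec: the same seed yields a
bit-identical fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structures import AtomRecord, ConformerSet, MoleculeStructure

__all__ = [
    "FixtureSpec",
    "ComplexFixture",
    "make_molecule",
    "make_complementary_pair",
    "make_complex_fixture",
    "make_screening_set",
]

_ELEMENT_CYCLE = ("C", "N", "O")
_ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52}
_BOND_LENGTH = 1.5
#: Blob-walk step and clash distance for rugged fixture ligands (Å).
_WALK_STEP = 1.8
_CLASH = 1.4
#: Surface-to-surface gap between ligand and cast wall (Å).
_CAST_GAP = 1.8
#: Fraction of the ligand height covered by the cast (cavity open at top).
_CUP_COVERAGE = 0.65
#: Minimum separation of cast wall atoms (Å).
_WALL_SPACING = 2.0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_atoms: int = 24
    cavity_radius: float = 7.0
    noise_sigma: float = 0.0
    charge_pattern: str = "dipolar"  # none | dipolar | random


def _walk_coords(
    rng: np.random.Generator, n_atoms: int, max_radius: float | None, step: float = _BOND_LENGTH
) -> np.ndarray:
    """Connected random walk, optionally confined to a ball, clash-avoiding."""
    clash = 1.0 if step < 1.6 else _CLASH
    coords = [np.zeros(3)]
    while len(coords) < n_atoms:
        s = rng.normal(size=3)
        s *= step / np.linalg.norm(s)
        base = coords[rng.integers(0, len(coords))] if len(coords) > 2 else coords[-1]
        cand = base + s
        if max_radius is not None and np.linalg.norm(cand) > max_radius:
            continue
        if any(np.linalg.norm(cand - c) < clash for c in coords):
            continue
        coords.append(cand)
    arr = np.array(coords)
    return arr - arr.mean(axis=0)


def _bonds_to_nearest(coords: np.ndarray) -> list[tuple[int, int, int]]:
    bonds = []
    for i in range(1, len(coords)):
        dists = np.linalg.norm(coords[:i] - coords[i], axis=1)
        bonds.append((int(np.argmin(dists)) + 1, i + 1, 1))
    return bonds


def _assign_charges(
    rng: np.random.Generator, coords: np.ndarray, pattern: str, scale: float = 0.3
) -> np.ndarray:
    if pattern == "none":
        return np.zeros(len(coords))
    if pattern == "dipolar":
        return np.where(coords[:, 2] > 0, scale, -scale)
    if pattern == "random":
        return rng.uniform(-0.5, 0.5, size=len(coords))
    raise ValueError(f"unknown charge pattern {pattern!r}")


def make_molecule(spec: FixtureSpec) -> MoleculeStructure:
    """Connected pseudo-molecule blob: 1.5 Å walk, C/N/O element cycle."""
    if spec.n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(spec.seed)
    coords = _walk_coords(rng, spec.n_atoms, None)
    charges = _assign_charges(rng, coords, spec.charge_pattern)
    atoms = []
    for i, (xyz, q) in enumerate(zip(coords, charges)):
        element = _ELEMENT_CYCLE[i % 3]
        atoms.append(
            AtomRecord(i + 1, f"{element}{i + 1}", element, xyz, float(q), _ELEMENT_RADII[element])
        )
    return MoleculeStructure(atoms, _bonds_to_nearest(coords), id=f"blob{spec.seed}")


def _rugged_ligand(rng: np.random.Generator, spec: FixtureSpec) -> MoleculeStructure:
    """Cavity-filling blob with varied atomic radii (rugged surface)."""
    max_r = max(spec.cavity_radius - 1.5, 1.6)
    coords = _walk_coords(rng, spec.n_atoms, max_r, step=_WALK_STEP)
    radii = rng.uniform(1.1, 2.3, size=spec.n_atoms)
    charge = {"dipolar": -0.25, "none": 0.0}.get(spec.charge_pattern)
    atoms = []
    for i, (xyz, r) in enumerate(zip(coords, radii)):
        element = _ELEMENT_CYCLE[i % 3]
        q = charge if charge is not None else float(rng.uniform(-0.4, 0.4))
        atoms.append(AtomRecord(i + 1, f"{element}{i + 1}", element, xyz, q, float(r)))
    return MoleculeStructure(atoms, _bonds_to_nearest(coords), id=f"lig{spec.seed}")


def _cast_protein(
    ligand_surface, spec: FixtureSpec, rng: np.random.Generator
) -> MoleculeStructure:
    """Double-layer wall cast onto the ligand surface, open at the top.

    Wall atom centers sit at ligand surface + normals * (gap + r_wall), so
    the wall's own surface leaves roughly a ``_CAST_GAP`` gap; a second
    layer 2.6 Å further out gives the wall thickness.
    """
    pts, normals = ligand_surface.points, ligand_surface.normals
    z = pts[:, 2]
    zcut = z.min() + (z.max() - z.min()) * _CUP_COVERAGE
    mask = z <= zcut
    centers = pts[mask] + normals[mask] * (_CAST_GAP + 1.7)
    outward = normals[mask]
    order = np.argsort(centers[:, 2])
    kept: list[int] = []
    for i in order:  # greedy thinning to wall atom spacing
        if all(np.linalg.norm(centers[i] - centers[j]) >= _WALL_SPACING for j in kept):
            kept.append(i)
    charge = {"dipolar": 0.25, "none": 0.0}.get(spec.charge_pattern)
    atoms = []
    for k, j in enumerate(kept):
        q = charge if charge is not None else float(rng.uniform(-0.4, 0.4))
        atoms.append(AtomRecord(k + 1, f"C{k + 1}", "C", centers[j], q, 1.7))
    n0 = len(atoms)
    for k, j in enumerate(kept):
        atoms.append(
            AtomRecord(n0 + k + 1, f"C{n0 + k + 1}", "C", centers[j] + outward[j] * 2.6, 0.0, 1.7)
        )
    return MoleculeStructure(atoms, id=f"cast{spec.seed}")


@dataclass
class ComplexFixture:
    """A toy complex with its processed surfaces, patches and true contacts."""

    protein: MoleculeStructure
    ligand: MoleculeStructure
    pocket_patches: "object"  # PatchSet
    ligand_patches: "object"  # PatchSet
    contact_map: "object"  # ContactMap
    true_contacts: list[tuple[int, int]]


def make_complex_fixture(spec: FixtureSpec, cutoff: float = 5.0) -> ComplexFixture:
    """Build a complementary pair and run the full pipeline on it.

    Returns the molecules, both descriptor-bearing patch sets (in the
    complex frame) and the native-contact map at ``cutoff``.  With
    ``noise_sigma > 0`` the ligand is jittered after the wall is cast,
    emulating an imperfect fit.
    """
    if spec.cavity_radius < 3.0:
        raise ValueError("cavity radius must be at least 3 Å")
    from .evaluate import ContactMap
    from .pipeline import RunConfig, build_patchset, build_surface
    from .pocket import ray_cast_pocket

    rng = np.random.default_rng(spec.seed)
    ligand = _rugged_ligand(rng, spec)
    cfg = RunConfig()
    lig_surface = build_surface(ligand, spacing=cfg.ligand_spacing)
    protein = _cast_protein(lig_surface, spec, rng)
    if spec.noise_sigma > 0:
        ligand = ligand.with_coords(
            ligand.coords + rng.normal(scale=spec.noise_sigma, size=(len(ligand.atoms), 3))
        )
        lig_surface = build_surface(ligand, spacing=cfg.ligand_spacing)
    prot_surface = build_surface(protein, spacing=cfg.protein_spacing)
    pocket = ray_cast_pocket(
        prot_surface,
        np.zeros(3),
        n_rays=cfg.n_rays,
        max_range=spec.cavity_radius + 8.0,
        protein_id=protein.id,
    )
    pocket_ps = build_patchset(pocket.surface, protein, cfg, source=f"{protein.id}:pocket")
    ligand_ps = build_patchset(lig_surface, ligand, cfg, source=ligand.id)
    cm = ContactMap(pocket_ps.centers, ligand_ps.centers, cutoff)
    return ComplexFixture(protein, ligand, pocket_ps, ligand_ps, cm, list(cm.contacts))


def make_complementary_pair(
    spec: FixtureSpec, cutoff: float = 5.0
) -> tuple[MoleculeStructure, MoleculeStructure, list[tuple[int, int]]]:
    """Cast-cavity protein, cavity-filling ligand, and their native patch contacts."""
    fx = make_complex_fixture(spec, cutoff)
    return fx.protein, fx.ligand, fx.true_contacts


def make_screening_set(
    spec: FixtureSpec,
    n_actives: int = 5,
    n_decoys: int = 45,
    n_conformers: int = 3,
    jitter_sigma: float = 0.35,
) -> tuple[list[ConformerSet], dict[str, bool]]:
    """Labeled toy screening library for the spec's cavity.

    Actives are jittered copies of the cavity-filling ligand; decoys are
    fresh random-walk blobs with the same atom count and radius
    distribution (similar size, different shape).  Each entry carries
    ``n_conformers`` jittered conformers.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(spec.seed)
    cognate = _rugged_ligand(rng, replace(spec, noise_sigma=0.0))
    library: list[ConformerSet] = []
    labels: dict[str, bool] = {}

    def jittered(mol: MoleculeStructure, sigma: float, new_id: str) -> MoleculeStructure:
        noise = rng.normal(scale=sigma, size=(len(mol.atoms), 3)) if sigma > 0 else 0.0
        return mol.with_coords(mol.coords + noise, new_id)

    for i in range(n_actives):
        lid = f"active{i:02d}"
        confs = [
            jittered(cognate, 0.0 if (i == 0 and k == 0) else jitter_sigma, f"{lid}_c{k}")
            for k in range(n_conformers)
        ]
        library.append(ConformerSet(lid, confs))
        labels[lid] = True
    for i in range(n_decoys):
        lid = f"decoy{i:02d}"
        dseed = int(rng.integers(0, 2**31 - 1))
        drng = np.random.default_rng(dseed)
        coords = _walk_coords(drng, spec.n_atoms, max(spec.cavity_radius - 1.5, 1.6), step=_WALK_STEP)
        radii = drng.uniform(1.1, 2.3, size=spec.n_atoms)
        charge = {"dipolar": -0.25, "none": 0.0}.get(spec.charge_pattern, 0.0)
        atoms = [
            AtomRecord(
                k + 1,
                f"{_ELEMENT_CYCLE[k % 3]}{k + 1}",
                _ELEMENT_CYCLE[k % 3],
                xyz,
                charge,
                float(r),
            )
            for k, (xyz, r) in enumerate(zip(coords, radii))
        ]
        base = MoleculeStructure(atoms, _bonds_to_nearest(coords), id=lid)
        confs = [jittered(base, jitter_sigma, f"{lid}_c{k}") for k in range(n_conformers)]
        library.append(ConformerSet(lid, confs))
        labels[lid] = False
    return library, labels
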