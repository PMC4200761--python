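"""End-to-end pipelines and run configuration.

The canonical workflow: molecular surface -> (pocket carving for the
protein) -> seed selection and patch segmentation -> per-patch Zernike
descriptors -> patch matching -> complementarity scoring.  ``RunConfig``
gathers every tunable with the published defaults.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .matching import DistanceWeights, Matching, OPTIMIZED_WEIGHTS, match_patches
from .patches import PatchSet, segment_patches, select_seed_points
from .pocket import Pocket, pocket_center, ray_cast_pocket
from .scoring import ScoreBreakdown, TotalWeights, TRAINED_TOTAL_WEIGHTS, score_pair
from .structures import MoleculeStructure, read_structure
from .surface import SurfacePointCloud, assign_electrostatics, compute_density_grid, extract_surface_points
from .zernike import DEFAULT_DIM, DEFAULT_ORDER, normalize_descriptor_set, patch_descriptor

__all__ = [
    "RunConfig",
    "build_surface",
    "build_patchset",
    "process_pocket",
    "process_ligand",
    "write_patchset_jsonl",
    "read_patchset_jsonl",
    "write_matching_tsv",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All pipeline parameters with their published/default values."""

    protein_spacing: float = 0.6
    ligand_spacing: float = 0.4
    iso_level: float = 1.0
    n_rays: int = 1000
    max_range: float = 12.0
    seed_atom_dist: float = 3.5
    seed_min_sep: float = 3.0
    patch_radius: float = 5.0
    order: int = DEFAULT_ORDER
    grid_dim: int = DEFAULT_DIM
    descriptor_norm: str = "surface_mean"  # surface_mean | per_patch | none
    distance_weights: DistanceWeights = field(default_factory=lambda: OPTIMIZED_WEIGHTS)
    total_weights: TotalWeights = field(default_factory=lambda: TRAINED_TOTAL_WEIGHTS)
    contact_cutoff: float = 5.0
    electrostatics: str = "coulomb_screened"
    seed: int = 0

    def show(self) -> str:
        d = asdict(self)
        return "\n".join(f"{k} = {v}" for k, v in d.items())


def build_surface(
    mol: MoleculeStructure,
    spacing: float = 0.6,
    iso: float = 1.0,
    electrostatics: str = "coulomb_screened",
    potential_grid=None,
) -> SurfacePointCloud:
    """Density grid -> isosurface -> electrostatic potential, in one call."""
    grid = compute_density_grid(mol, spacing)
    surface = extract_surface_points(grid, iso, source_id=mol.id)
    if electrostatics == "none":
        return surface
    mode = "from_grid" if potential_grid is not None else electrostatics
    return assign_electrostatics(surface, mol, mode=mode, grid=potential_grid)


def build_patchset(
    surface: SurfacePointCloud,
    mol: MoleculeStructure,
    cfg: RunConfig | None = None,
    source: str = "",
) -> PatchSet:
    """Seeds -> patches -> geodesics/APP -> Zernike descriptors.

    Descriptor normalization follows ``cfg.descriptor_norm``: "surface_mean"
    (default) rescales by per-surface mean norms, "per_patch" divides each
    channel by its own F_00, "none" leaves raw moment norms.
    """
    cfg = cfg or RunConfig()
    seeds = select_seed_points(surface, mol, cfg.seed_atom_dist, cfg.seed_min_sep)
    ps = segment_patches(surface, seeds, cfg.patch_radius, source=source or mol.id)
    per_patch = cfg.descriptor_norm == "per_patch"
    descs = [
        patch_descriptor(p, surface, cfg.order, cfg.grid_dim, normalize=per_patch)
        for p in ps.patches
    ]
    if cfg.descriptor_norm == "surface_mean":
        descs = normalize_descriptor_set(descs)
    elif cfg.descriptor_norm not in {"per_patch", "none"}:
        raise ValueError(f"unknown descriptor_norm {cfg.descriptor_norm!r}")
    for patch, d in zip(ps.patches, descs):
        patch.descriptor = d
    return ps


def process_pocket(
    protein: MoleculeStructure,
    bound_ligand: MoleculeStructure,
    cfg: RunConfig | None = None,
    potential_grid=None,
) -> tuple[Pocket, PatchSet]:
    """Protein + bound ligand -> pocket patches with descriptors."""
    cfg = cfg or RunConfig()
    surface = build_surface(
        protein, cfg.protein_spacing, cfg.iso_level, cfg.electrostatics, potential_grid
    )
    center = pocket_center(bound_ligand)
    pocket = ray_cast_pocket(surface, center, cfg.n_rays, cfg.max_range, protein_id=protein.id)
    ps = build_patchset(pocket.surface, protein, cfg, source=f"{protein.id}:pocket")
    return pocket, ps


def process_ligand(ligand: MoleculeStructure, cfg: RunConfig | None = None) -> PatchSet:
    """Ligand conformer -> patch set with descriptors."""
    cfg = cfg or RunConfig()
    surface = build_surface(ligand, cfg.ligand_spacing, cfg.iso_level, cfg.electrostatics)
    return build_patchset(surface, ligand, cfg, source=ligand.id)


# ---------------------------------------------------------------------------
# Serialization


def write_patchset_jsonl(ps: PatchSet, path) -> None:
    """One JSON object per patch: seed, members, APP bins, descriptors."""
    lines = [
        json.dumps(
            {
                "source": ps.source,
                "n_patches": len(ps),
                "geodesic": np.where(np.isfinite(ps.geodesic), ps.geodesic, -1.0).round(6).tolist(),
                "euclidean": ps.euclidean.round(6).tolist(),
            },
            sort_keys=True,
        )
    ]
    for patch, app in zip(ps.patches, ps.app):
        d = patch.descriptor
        rec = {
            "id": patch.id,
            "seed_index": int(patch.seed_index),
            "seed": patch.seed.round(6).tolist(),
            "members": patch.point_ids.tolist(),
            "app": app.tolist(),
        }
        if d is not None:
            rec["shape"] = np.round(d.shape, 9).tolist()
            rec["elec_pos"] = np.round(d.elec_pos, 9).tolist()
            rec["elec_neg"] = np.round(d.elec_neg, 9).tolist()
            rec["order"] = d.order
        lines.append(json.dumps(rec, sort_keys=True))
    Path(path).write_text("\n".join(lines) + "\n")


def read_patchset_jsonl(path) -> PatchSet:
    from .patches import Patch
    from .zernike import ZernikeDescriptor

    lines = Path(path).read_text().splitlines()
    header = json.loads(lines[0])
    geo = np.array(header["geodesic"])
    geo[geo < 0] = np.inf
    patches = []
    apps = []
    for line in lines[1:]:
        rec = json.loads(line)
        p = Patch(
            rec["id"],
            rec["seed_index"],
            np.array(rec["seed"]),
            np.array(rec["members"], dtype=int),
        )
        if "shape" in rec:
            p.descriptor = ZernikeDescriptor(
                np.array(rec["shape"]),
                np.array(rec["elec_pos"]),
                np.array(rec["elec_neg"]),
                rec.get("order", DEFAULT_ORDER),
            )
        patches.append(p)
        apps.append(rec["app"])
    ps = PatchSet(patches, geo, np.array(header["euclidean"]), source=header.get("source", ""))
    ps.app = np.array(apps, dtype=int)
    return ps


def write_matching_tsv(m: Matching, path) -> None:
    lines = ["pocket_patch\tligand_patch\tpdist\tappd\tgrpd\ttotal"]
    for (i, j), pd_, ad_, gd_, tot in zip(m.pairs, m.pdist, m.appd, m.grpd, m.total):
        lines.append(f"{i}\t{j}\t{pd_:.6f}\t{ad_:.6f}\t{gd_:.6f}\t{tot:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    protein_path,
    ligand_path,
    out_dir,
    cfg: RunConfig | None = None,
) -> dict:
    """File-to-file pipeline: structures in, matching TSV + score JSON out."""
    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protein = read_structure(protein_path)
    ligand = read_structure(ligand_path)
    _, pocket_ps = process_pocket(protein, ligand, cfg)
    ligand_ps = process_ligand(ligand, cfg)
    write_patchset_jsonl(pocket_ps, out / "pocket_patches.jsonl")
    write_patchset_jsonl(ligand_ps, out / "ligand_patches.jsonl")
    m = match_patches(pocket_ps, ligand_ps, cfg.distance_weights)
    write_matching_tsv(m, out / "matching.tsv")
    breakdown = score_pair(
        pocket_ps, ligand_ps, cfg.distance_weights, cfg.total_weights, "pl", matching=m
    )
    score = {
        "avg_zd": breakdown.avg_zd,
        "avg_grpd": breakdown.avg_grpd,
        "pocket_sd": breakdown.pocket_sd,
        "total": breakdown.total,
        "n_pocket_patches": len(pocket_ps),
        "n_ligand_patches": len(ligand_ps),
        "n_matched_pairs": m.n_pairs,
    }
    (out / "score.json").write_text(json.dumps(score, sort_keys=True, indent=2) + "\n")
    return score
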