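"""Binding-pocket definition by ray casting from the bound-ligand centroid.

The pocket center is the mass-weighted centroid of the bound ligand's
heavy atoms.  Rays on a Fibonacci sphere are cast from the center; the
first surface point each ray meets is kept, and the hit set is dilated by
one adjacency ring to close pinholes between rays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import MoleculeStructure
from .surface import SurfacePointCloud

__all__ = ["Pocket", "pocket_center", "fibonacci_sphere", "ray_cast_pocket"]


class EmptyPocketError(RuntimeError):
    pass


@dataclass
class Pocket:
    center: np.ndarray
    surface: SurfacePointCloud
    parent_indices: np.ndarray
    protein_id: str = ""


def pocket_center(ligand: MoleculeStructure) -> np.ndarray:
    """Center of mass of the ligand's heavy atoms (standard atomic masses)."""
    heavy = ligand.heavy_atoms()
    if not heavy:
        raise ValueError("ligand has no heavy atoms")
    masses = np.array([a.mass for a in heavy])
    coords = np.array([a.coords for a in heavy])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit directions."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def ray_cast_pocket(
    surface: SurfacePointCloud,
    center: np.ndarray,
    n_rays: int = 1000,
    max_range: float = 12.0,
    hit_tol: float | None = None,
    protein_id: str = "",
) -> Pocket:
    """Carve the pocket surface as the first-hit points of rays from the center.

    A surface point is hit by a ray when it lies within ``hit_tol`` of the
    ray segment (default 1.2x the median mesh edge length) and within
    ``max_range`` of the center; only the nearest hit per ray is kept
    (pocket walls, not the far side).  Hits are dilated by one adjacency
    ring to close gaps between neighbouring rays.
    """
    center = np.asarray(center, dtype=float)
    if hit_tol is None:
        hit_tol = 1.2 * surface.median_edge_length()
    rel = surface.points - center
    dist2 = np.einsum("ij,ij->i", rel, rel)
    in_range = dist2 <= max_range * max_range
    if not np.any(in_range):
        raise EmptyPocketError("no surface point within max_range of the pocket center")
    idx_range = np.nonzero(in_range)[0]
    rel = rel[idx_range]
    dirs = fibonacci_sphere(n_rays)
    hits: set[int] = set()
    # chunk rays to bound the (points x rays) projection matrix
    for start in range(0, n_rays, 128):
        block = dirs[start : start + 128]
        t = rel @ block.T                       # (points, rays) projections
        perp2 = dist2[idx_range][:, None] - t * t
        ok = (t >= 0) & (t <= max_range) & (perp2 <= hit_tol * hit_tol)
        t_masked = np.where(ok, t, np.inf)
        first = np.argmin(t_masked, axis=0)
        ray_has_hit = np.isfinite(t_masked[first, np.arange(block.shape[0])])
        hits.update(int(idx_range[f]) for f, h in zip(first, ray_has_hit) if h)
    if not hits:
        raise EmptyPocketError("rays hit no surface points")
    hit_idx = np.fromiter(hits, dtype=int)
    neighbor_mask = np.zeros(len(surface), dtype=bool)
    neighbor_mask[hit_idx] = True
    ring = surface.adjacency[hit_idx].tocoo().col  # one-ring dilation
    neighbor_mask[ring] = True
    indices = np.sort(np.nonzero(neighbor_mask)[0])
    return Pocket(center, surface.subset(indices, source_id=f"{protein_id}:pocket"), indices, protein_id)
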