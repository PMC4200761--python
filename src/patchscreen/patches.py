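"""Seed selection, patch segmentation, geodesics and patch-position vectors.

A patch is a connected surface region within a fixed geodesic radius
(default 5.0 Å) of a seed point.  Seeds are the surface points nearest to
heavy atoms lying within 3.5 Å of the surface, accepted in order of
increasing atom-to-surface distance under a 3.0 Å mutual-separation
constraint, which distributes patches evenly over the region.

The approximate patch position (APP) vector of a patch is a 40-bin,
1 Å-wide histogram of its geodesic distances to all other patches: it
encodes whether a patch sits centrally or peripherally, independent of
any reference frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .structures import MoleculeStructure
from .surface import SurfacePointCloud

__all__ = [
    "Patch",
    "PatchSet",
    "select_seed_points",
    "segment_patches",
    "geodesic_matrix",
    "app_vectors",
    "APP_BINS",
    "APP_BIN_WIDTH",
]

APP_BINS = 40
APP_BIN_WIDTH = 1.0
#: Cap used in place of an infinite geodesic distance (Å).
GEODESIC_CAP = 40.0


@dataclass
class Patch:
    id: int
    seed_index: int
    seed: np.ndarray
    point_ids: np.ndarray
    descriptor: "object | None" = None  # ZernikeDescriptor, attached later

    @property
    def center(self) -> np.ndarray:
        """The seed surface point; used for all inter-patch distances."""
        return self.seed


@dataclass
class PatchSet:
    patches: list[Patch]
    geodesic: np.ndarray
    euclidean: np.ndarray
    app: np.ndarray = field(default=None)
    source: str = ""

    def __post_init__(self) -> None:
        if self.app is None:
            self.app = app_vectors(self)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.patches])

    @property
    def descriptors(self) -> list:
        return [p.descriptor for p in self.patches]


def select_seed_points(
    surface: SurfacePointCloud,
    mol: MoleculeStructure,
    d_atom: float = 3.5,
    d_min: float = 3.0,
) -> np.ndarray:
    """Pick patch seed points from the surface.

    Heavy atoms within ``d_atom`` of the surface are visited in ascending
    atom-to-surface distance (ties broken by atom serial); each contributes
    its closest surface point as a seed unless that point lies within
    ``d_min`` of an already accepted seed.
    """
    if len(surface) == 0:
        raise ValueError("empty surface")
    heavy = mol.heavy_atoms()
    if not heavy:
        raise ValueError("molecule has no heavy atoms")
    tree = cKDTree(surface.points)
    coords = np.array([a.coords for a in heavy])
    dists, nearest = tree.query(coords)
    order = sorted(range(len(heavy)), key=lambda i: (dists[i], heavy[i].serial))
    seeds: list[int] = []
    for i in order:
        if dists[i] > d_atom:
            continue
        candidate = int(nearest[i])
        p = surface.points[candidate]
        if all(np.linalg.norm(p - surface.points[s]) >= d_min for s in seeds):
            seeds.append(candidate)
    if not seeds:
        raise ValueError(f"no heavy atom lies within {d_atom} Å of the surface")
    return np.array(seeds, dtype=int)


def segment_patches(
    surface: SurfacePointCloud,
    seeds: np.ndarray,
    radius: float = 5.0,
    mode: str = "geodesic",
    source: str = "",
) -> PatchSet:
    """Segment the surface into seed-centered patches.

    ``geodesic`` mode (default) takes all points within ``radius`` of the
    seed along the surface graph, which guarantees each patch is a single
    connected region.  ``euclidean`` mode takes the Euclidean ball and
    keeps the connected component containing the seed.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise ValueError("at least one seed is required")
    if seeds.max() >= len(surface) or seeds.min() < 0:
        raise IndexError("seed index outside surface")
    if mode == "geodesic":
        dmat = dijkstra(surface.adjacency, directed=False, indices=seeds, limit=radius)
        members = [np.nonzero(np.isfinite(dmat[k]))[0] for k in range(len(seeds))]
    elif mode == "euclidean":
        members = []
        dmat_all = dijkstra(surface.adjacency, directed=False, indices=seeds)
        for k, s in enumerate(seeds):
            ball = np.linalg.norm(surface.points - surface.points[s], axis=1) <= radius
            connected = np.isfinite(dmat_all[k])
            members.append(np.nonzero(ball & connected)[0])
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    patches = [
        Patch(k, int(s), surface.points[s].copy(), m)
        for k, (s, m) in enumerate(zip(seeds, members))
    ]
    geo = geodesic_matrix(seeds, surface)
    centers = surface.points[seeds]
    euc = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    return PatchSet(patches, geo, euc, source=source)


def geodesic_matrix(seeds: np.ndarray, surface: SurfacePointCloud) -> np.ndarray:
    """Seed-to-seed shortest-path distances over the surface edge graph.

    Entries between disconnected components are +inf; callers bin or cap
    them explicitly.
    """
    seeds = np.asarray(seeds, dtype=int)
    dmat = dijkstra(surface.adjacency, directed=False, indices=seeds)
    geo = dmat[:, seeds]
    np.fill_diagonal(geo, 0.0)
    return geo


def app_vectors(patchset: PatchSet) -> np.ndarray:
    """Approximate-patch-position histograms, one row per patch.

    Bin index = floor(geodesic / 1 Å), clipped to [0, 39]; infinite
    distances land in the last bin with a warning.  Rows sum to P - 1.
    """
    geo = patchset.geodesic
    n = geo.shape[0]
    app = np.zeros((n, APP_BINS), dtype=int)
    if n > 1 and not np.all(np.isfinite(geo)):
        warnings.warn("infinite geodesic distances binned into the last APP bin", stacklevel=2)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = geo[i, j]
            b = APP_BINS - 1 if not np.isfinite(d) else min(int(d // APP_BIN_WIDTH), APP_BINS - 1)
            app[i, b] += 1
    return app
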