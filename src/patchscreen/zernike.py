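"""Rotation-invariant 3D Zernike descriptors of surface patches.

A patch is rasterised into a cubic voxel grid inside the unit ball
(farthest point mapped to radius 0.7), once for shape (binary occupancy)
and twice for electrostatics (positive and negative potential magnitudes
as two non-negative channels).  The voxel function f is expanded in the
Zernike-Canterakis basis Z_nlm(r, theta, phi) = R_nl(r) Y_lm(theta, phi):

    Omega_nlm = (3 / 4pi) * integral_ball f(x) * conj(Z_nlm(x)) dx

and the rotation-invariant descriptor collects the per-(n, l) norms

    F_nl = sqrt( sum_m |Omega_nlm|^2 ).

With expansion order n = 15 there are 72 valid (n, l) pairs (l <= n,
n - l even), so shape gives a 72-vector and the two electrostatic
channels together a 144-vector.

The radial polynomials R_nl(r) = sum_v q_v r^(l + 2v) are constructed by
exact Gram-Schmidt orthonormalisation (rational arithmetic) of the
monomials r^l, r^(l+2), ... under the ball measure 3 r^2 dr on [0, 1],
with the leading coefficient taken positive.  Per-(n, l) sign conventions
do not affect the norms F_nl.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "UnitSphereFunction",
    "ZernikeMoments",
    "ZernikeDescriptor",
    "descriptor_length",
    "nl_pairs",
    "radial_coefficients",
    "voxelize_patch",
    "zernike_moments",
    "invariant_norms",
    "patch_descriptor",
]

DEFAULT_ORDER = 15
DEFAULT_DIM = 64
#: Standard practice: map the farthest point to radius 0.7 of the unit ball.
UNIT_SPHERE_SCALE = 0.7
MAX_ORDER = 20


def nl_pairs(order: int) -> list[tuple[int, int]]:
    """Valid (n, l) index pairs: 0 <= l <= n <= order, n - l even."""
    if order < 0:
        raise ValueError("expansion order must be non-negative")
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def descriptor_length(order: int) -> int:
    """Number of rotation invariants at a given expansion order."""
    return len(nl_pairs(order))


@lru_cache(maxsize=None)
def radial_coefficients(order: int) -> dict[tuple[int, int], np.ndarray]:
    """Coefficients q of R_nl(r) = sum_v q[v] * r^(l + 2v), orthonormal under
    3 * integral_0^1 R_nl R_n'l r^2 dr = delta_nn'."""
    coeffs: dict[tuple[int, int], np.ndarray] = {}
    for l in range(order + 1):
        n_polys = (order - l) // 2 + 1
        # exact Gram-Schmidt on monomial coefficient vectors (orthogonal, not
        # yet normalised); inner product uses 3*int r^(l+2i) r^(l+2j) r^2 dr
        basis: list[list[Fraction]] = []
        for k in range(n_polys):
            vec = [Fraction(0)] * n_polys
            vec[k] = Fraction(1)
            for prev in basis:
                proj = _radial_inner(vec, prev, l) / _radial_inner(prev, prev, l)
                vec = [v - proj * p for v, p in zip(vec, prev)]
            basis.append(vec)
            norm = float(_radial_inner(vec, vec, l)) ** 0.5
            arr = np.array([float(v) for v in vec]) / norm
            if arr[k] < 0:  # leading (highest-degree) coefficient positive
                arr = -arr
            coeffs[(l + 2 * k, l)] = arr[: k + 1]
    return coeffs


def _radial_inner(a: list[Fraction], b: list[Fraction], l: int) -> Fraction:
    total = Fraction(0)
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        for j, bj in enumerate(b):
            if bj == 0:
                continue
            total += ai * bj * Fraction(3, 2 * l + 2 * i + 2 * j + 3)
    return total


@dataclass
class UnitSphereFunction:
    """Scalar function sampled on a cubic voxel grid inside the unit ball."""

    grid: np.ndarray
    scale: float  # Å per unit-ball radius unit
    offset: np.ndarray  # patch centroid (Å)

    @property
    def dim(self) -> int:
        return self.grid.shape[0]

    def nonzero_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, unit-ball xyz of voxel centers) for nonzero voxels."""
        idx = np.argwhere(self.grid != 0)
        vals = self.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        xyz = (idx + 0.5) * (2.0 / self.dim) - 1.0
        return vals, xyz


@dataclass
class ZernikeMoments:
    """Complex moments Omega_nlm for m >= 0 (f real: Omega_{n,l,-m} =
    (-1)^m conj(Omega_nlm))."""

    order: int
    data: dict[tuple[int, int], np.ndarray]  # (n, l) -> complex array over m = 0..l


@dataclass
class ZernikeDescriptor:
    shape: np.ndarray
    elec_pos: np.ndarray
    elec_neg: np.ndarray
    order: int = DEFAULT_ORDER

    @property
    def elec(self) -> np.ndarray:
        """The 144-length electrostatic descriptor (positive + negative channels)."""
        return np.concatenate([self.elec_pos, self.elec_neg])


def voxelize_patch(
    patch,
    surface,
    channel: str = "shape",
    dim: int = DEFAULT_DIM,
    mode: str = "trilinear",
) -> UnitSphereFunction:
    """Rasterise a patch into the unit ball.

    Per-point values are 1 for the shape channel, max(phi, 0) for
    elec_pos and |min(phi, 0)| for elec_neg.  The grid is centered at the
    patch centroid and scaled so the farthest point sits at radius 0.7.

    ``trilinear`` (default) splats each point's value onto its eight
    surrounding voxels with trilinear weights, which suppresses the
    lattice discretisation noise that otherwise dominates the rotational
    error of the invariants.  ``nearest`` sets the single nearest voxel
    (colliding points keep the largest value).
    """
    pts = surface.points[patch.point_ids]
    if len(pts) < 3:
        raise ValueError("patch has fewer than 3 points")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    rmax = float(np.linalg.norm(rel, axis=1).max())
    if rmax <= 0:
        raise ValueError("degenerate patch: all points identical")
    unit = rel * (UNIT_SPHERE_SCALE / rmax)
    if channel == "shape":
        vals = np.ones(len(pts))
    elif channel == "elec_pos":
        vals = np.maximum(surface.potential[patch.point_ids], 0.0)
    elif channel == "elec_neg":
        vals = np.abs(np.minimum(surface.potential[patch.point_ids], 0.0))
    else:
        raise ValueError(f"unknown channel {channel!r}")
    grid = np.zeros((dim, dim, dim))
    if mode == "nearest":
        idx = np.clip(((unit + 1.0) * (dim / 2.0)).astype(int), 0, dim - 1)
        for (i, j, k), v in zip(idx, vals):
            grid[i, j, k] = max(grid[i, j, k], v)
    elif mode == "trilinear":
        g = (unit + 1.0) * (dim / 2.0) - 0.5
        i0 = np.floor(g).astype(int)
        frac = g - i0
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
            ii = np.clip(i0 + off, 0, dim - 1)
            np.add.at(grid, (ii[:, 0], ii[:, 1], ii[:, 2]), w * vals)
    else:
        raise ValueError(f"unknown voxelization mode {mode!r}")
    return UnitSphereFunction(grid, rmax / UNIT_SPHERE_SCALE, centroid)


def spherical_harmonics_table(order: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal spherical harmonics Y_lm for all 0 <= m <= l <= order.

    Returns a complex array of shape (order+1, order+1, len(theta)) indexed
    [l, m]; entries with m > l are zero.  Uses the standard stable upward
    recurrence on fully normalised associated Legendre functions with the
    Condon-Shortley phase (matching scipy's convention); evaluating the
    whole table in one vectorised pass is much cheaper than per-(l, m)
    library calls.
    """
    ct = np.cos(theta)
    st = np.sin(theta)
    n_pts = len(ct)
    p = np.zeros((order + 1, order + 1, n_pts))
    p[0, 0] = np.sqrt(1.0 / (4.0 * np.pi))
    for m in range(1, order + 1):  # diagonal: P~_m^m
        p[m, m] = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * st * p[m - 1, m - 1]
    for m in range(order):  # first superdiagonal: P~_{m+1}^m
        p[m + 1, m] = np.sqrt(2.0 * m + 3.0) * ct * p[m, m]
    for m in range(order + 1):
        for l in range(m + 2, order + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            p[l, m] = a * (ct * p[l - 1, m] - b * p[l - 2, m])
    phase = np.exp(1j * np.outer(np.arange(order + 1), phi))  # (m, pts)
    return p * phase[None, :, :]


def _zero_moments(order: int) -> ZernikeMoments:
    return ZernikeMoments(
        order, {(n, l): np.zeros(l + 1, dtype=complex) for n, l in nl_pairs(order)}
    )


def zernike_moments_multi(
    xyz: np.ndarray, value_rows: np.ndarray, dv: float, order: int = DEFAULT_ORDER
) -> list[ZernikeMoments]:
    """Moments of several functions sharing one voxel support.

    ``xyz`` holds unit-ball voxel centers (vox, 3); each row of
    ``value_rows`` (n_functions, vox) is projected onto the basis:
    Omega_nlm = (3/4pi) sum_vox f * conj(Z_nlm) * dV.  Evaluating the
    harmonic and radial factors once for all functions (and all m via the
    recurrence in ``spherical_harmonics_table``) is what makes per-patch
    descriptors cheap.
    """
    if order > MAX_ORDER:
        raise ValueError(f"expansion order above {MAX_ORDER} is numerically unsupported")
    value_rows = np.atleast_2d(value_rows)
    if xyz.shape[0] == 0:
        return [_zero_moments(order) for _ in range(value_rows.shape[0])]
    r = np.linalg.norm(xyz, axis=1)
    r_safe = np.maximum(r, 1e-12)
    theta = np.arccos(np.clip(xyz[:, 2] / r_safe, -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    ylm = spherical_harmonics_table(order, theta, phi)  # (l, m>=0, vox)
    rad_coeffs = radial_coefficients(order)
    rpow = np.vander(r, order + 1, increasing=True)  # (vox, order+1)
    weighted = value_rows * (dv * 3.0 / (4.0 * np.pi))  # (fn, vox)
    n_fn = value_rows.shape[0]
    out = [ZernikeMoments(order, {}) for _ in range(n_fn)]
    for l in range(order + 1):
        ns = list(range(l, order + 1, 2))
        if not ns:
            continue
        # all radial polynomials sharing this l, evaluated in one matmul
        radial = np.zeros((len(ns), rpow.shape[0]))
        for k, n in enumerate(ns):
            q = rad_coeffs[(n, l)]
            radial[k] = rpow[:, l + 2 * np.arange(len(q))] @ q
        y_t = ylm[l, : l + 1].T  # (vox, m); conj folded in via the sign of imag
        # proj[f*n, m] = sum_vox weighted[f] * radial[n] * conj(Y_lm): two real GEMMs
        fr = (weighted[:, None, :] * radial[None, :, :]).reshape(n_fn * len(ns), -1)
        proj = (fr @ y_t.real - 1j * (fr @ y_t.imag)).reshape(n_fn, len(ns), l + 1)
        for f in range(n_fn):
            for k, n in enumerate(ns):
                out[f].data[(n, l)] = proj[f, k]
    return out


def zernike_moments(f: UnitSphereFunction, order: int = DEFAULT_ORDER) -> ZernikeMoments:
    """Zernike-Canterakis moments of a unit-ball voxel function.

    Direct projection over nonzero voxels; stable for order <= 20.
    """
    vals, xyz = f.nonzero_coords()
    if len(vals) == 0:
        warnings.warn("empty function: all moments zero", stacklevel=2)
        return _zero_moments(order)
    dv = (2.0 / f.dim) ** 3
    return zernike_moments_multi(xyz, vals[None, :], dv, order)[0]


def invariant_norms(moments: ZernikeMoments) -> np.ndarray:
    """Per-(n, l) norms F_nl = sqrt(sum_m |Omega_nlm|^2), ordered by
    ascending n then l (length descriptor_length(order))."""
    out = []
    for n, l in nl_pairs(moments.order):
        omega = moments.data[(n, l)]
        # real f: |Omega_{n,l,-m}| = |Omega_{n,l,m}|
        total = np.abs(omega[0]) ** 2 + 2.0 * np.sum(np.abs(omega[1:]) ** 2)
        out.append(np.sqrt(total))
    return np.array(out)


def patch_descriptor(
    patch,
    surface,
    order: int = DEFAULT_ORDER,
    dim: int = DEFAULT_DIM,
    normalize: bool = False,
) -> ZernikeDescriptor:
    """Shape + split-sign electrostatic Zernike invariants of one patch.

    With ``normalize`` each channel is divided by its own F_00 (when
    positive) so the descriptor compares distributions rather than sizes.
    The pipeline default instead rescales whole patch sets by per-surface
    mean norms (see :func:`normalize_descriptor_set`), which keeps the
    relative patch-size information that per-patch normalization discards.
    """
    grids = {c: voxelize_patch(patch, surface, c, dim) for c in ("shape", "elec_pos", "elec_neg")}
    # all channels share the shape channel's splat support
    idx = np.argwhere(grids["shape"].grid != 0)
    xyz = (idx + 0.5) * (2.0 / dim) - 1.0
    rows = np.stack([grids[c].grid[idx[:, 0], idx[:, 1], idx[:, 2]] for c in grids], axis=0)
    dv = (2.0 / dim) ** 3
    moments = zernike_moments_multi(xyz, rows, dv, order)
    channels = {}
    for c, m in zip(grids, moments):
        desc = invariant_norms(m)
        if normalize and desc[0] > 0:
            desc = desc / desc[0]
        channels[c] = desc
    return ZernikeDescriptor(channels["shape"], channels["elec_pos"], channels["elec_neg"], order)


def normalize_descriptor_set(descriptors: list[ZernikeDescriptor]) -> list[ZernikeDescriptor]:
    """Rescale a surface's patch descriptors by per-surface mean norms.

    The shape channels are divided by the mean shape F_00 across patches,
    and both electrostatic channels by the mean combined (pos + neg) F_00.
    This cancels the systematic dependence on surface point density —
    pocket and ligand surfaces are meshed at different resolutions — while
    preserving the relative size and potential strength of patches within
    a surface, which carry correspondence information.  The positive and
    negative channels share one scale so the sign asymmetry survives.
    """
    if not descriptors:
        return []
    shape_scale = float(np.mean([d.shape[0] for d in descriptors])) or 1.0
    elec_scale = float(np.mean([d.elec_pos[0] + d.elec_neg[0] for d in descriptors])) or 1.0
    return [
        ZernikeDescriptor(
            d.shape / shape_scale, d.elec_pos / elec_scale, d.elec_neg / elec_scale, d.order
        )
        for d in descriptors
    ]
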