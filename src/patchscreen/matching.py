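"""Patch-pair distance scoring and auction assignment of pocket vs ligand.

The distance between pocket patch a and ligand patch b is a weighted sum
of three terms:

    distance(a, b) = w1 * pdist(a, b) + w2 * appd(a, b) + w3 * grpd(a, b)

pdist compares the 3D Zernike descriptors (0.717 * shape L2 + 0.283 *
electrostatics L2), appd the approximate-patch-position histograms, and
grpd the consistency of the pair's geodesic distances to already-matched
pairs.  Because grpd depends on the current pair list, matching proceeds
in phases: an assignment is first found with grpd ignored, then costs are
recomputed against the previous assignment and re-solved until the pair
set is stable (at most five rounds).

Each phase is a minimum-cost one-to-one assignment solved with an
epsilon-scaling auction: unassigned row patches repeatedly bid for their
best column patch at a price increment equal to the gap between best and
second-best value plus epsilon; epsilon shrinks geometrically until the
integer-scaled solution is exactly optimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .patches import GEODESIC_CAP, PatchSet
from .zernike import ZernikeDescriptor

__all__ = [
    "PDIST_SHAPE_WEIGHT",
    "PDIST_ELEC_WEIGHT",
    "DistanceWeights",
    "Matching",
    "pdist",
    "appd",
    "grpd",
    "distance_score",
    "auction_assign",
    "match_patches",
]

#: Fixed weights normalising shape vs electrostatics contributions in pdist.
PDIST_SHAPE_WEIGHT = 0.717
PDIST_ELEC_WEIGHT = 0.283

#: Integer cost scaling for exact auction termination.
_COST_SCALE = 1e6


@dataclass(frozen=True)
class DistanceWeights:
    """Weights of the three patch-distance terms (pdist, appd, grpd)."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("distance weights must be non-negative")

    @classmethod
    def from_ab(cls, a: float, b: float) -> "DistanceWeights":
        """Two-parameter form (w1, w2, w3) = (a*b, a*(1-b), 1-a); sums to 1."""
        return cls(a * b, a * (1.0 - b), 1.0 - a)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


#: Weights tuned for pocket-to-pocket comparison (carried over default).
DEFAULT_WEIGHTS = DistanceWeights(0.32, 0.48, 0.2)
#: Weights optimised for pocket-to-ligand matching.
OPTIMIZED_WEIGHTS = DistanceWeights(0.35, 0.15, 0.5)
#: Descriptor-only distance used by the pocket-similarity style scoring.
PS_WEIGHTS = DistanceWeights(1.0, 0.0, 0.0)


@dataclass
class Matching:
    """One-to-one pocket/ligand patch correspondence with per-pair terms."""

    pairs: list[tuple[int, int]]  # (pocket patch id, ligand patch id)
    pdist: np.ndarray
    appd: np.ndarray
    grpd: np.ndarray
    weights: DistanceWeights

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total(self) -> np.ndarray:
        w = self.weights
        return w.w1 * self.pdist + w.w2 * self.appd + w.w3 * self.grpd

    def pocket_ids(self) -> np.ndarray:
        return np.array([p for p, _ in self.pairs], dtype=int)

    def ligand_ids(self) -> np.ndarray:
        return np.array([l for _, l in self.pairs], dtype=int)


def pdist(a: ZernikeDescriptor, b: ZernikeDescriptor) -> float:
    """Weighted descriptor distance: 0.717*L2(shape) + 0.283*L2(elec)."""
    if len(a.shape) != len(b.shape) or len(a.elec) != len(b.elec):
        raise ValueError("descriptor length mismatch")
    return float(
        PDIST_SHAPE_WEIGHT * np.linalg.norm(a.shape - b.shape)
        + PDIST_ELEC_WEIGHT * np.linalg.norm(a.elec - b.elec)
    )


def appd(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two approximate-patch-position vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("APP vector length mismatch")
    return float(np.linalg.norm(a - b))


def _capped(d: float) -> float:
    if not np.isfinite(d):
        warnings.warn(f"infinite geodesic capped at {GEODESIC_CAP} Å", stacklevel=3)
        return GEODESIC_CAP
    return d


def grpd(
    a: int,
    b: int,
    m: list[tuple[int, int]],
    g2_a: np.ndarray,
    g2_b: np.ndarray,
) -> float:
    """Geodesic relative-position difference of candidate pair (a, b) against
    the already-matched pairs m; 0 when m is empty (term ignored)."""
    couples = [(ap, bp) for ap, bp in m if ap != a and bp != b]
    if not couples:
        return 0.0
    total = sum(abs(_capped(g2_a[a, ap]) - _capped(g2_b[b, bp])) for ap, bp in couples)
    return total / len(couples)


def distance_score(
    pdist_val: float, appd_val: float, grpd_val: float, w: DistanceWeights
) -> float:
    return w.w1 * pdist_val + w.w2 * appd_val + w.w3 * grpd_val


# ---------------------------------------------------------------------------
# Auction assignment


def auction_assign(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost one-to-one assignment of every row to a distinct column.

    Requires n_rows <= n_cols.  Costs are scaled to integers (x 1e6) and an
    epsilon-scaling forward auction is run: epsilon starts at max|cost|/2
    and is divided by 5 until below 1/(n+1), at which point the assignment
    is optimal for the scaled integer costs.

    Returns an array ``col_of_row`` of length n_rows.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2D matrix")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    n_rows, n_cols = cost.shape
    if n_rows > n_cols:
        raise ValueError("auction_assign requires n_rows <= n_cols; transpose first")
    if n_rows < n_cols:
        # pad with zero-cost dummy rows: the square optimum restricted to the
        # real rows is the optimal injective assignment (forward auction alone
        # is not optimality-safe on asymmetric problems)
        padded = np.vstack([cost, np.zeros((n_cols - n_rows, n_cols))])
        return auction_assign(padded)[:n_rows]
    benefit = -np.round(cost * _COST_SCALE)
    prices = np.zeros(n_cols)
    assignment = np.full(n_rows, -1, dtype=int)
    owner = np.full(n_cols, -1, dtype=int)
    eps = max(np.abs(benefit).max() / 2.0, 1.0)
    eps_final = 1.0 / (n_cols + 1)
    while True:
        assignment.fill(-1)
        owner.fill(-1)
        _auction_round(benefit, prices, assignment, owner, eps)
        if eps <= eps_final:
            break
        eps = max(eps / 5.0, eps_final)
    return assignment


def _auction_round(
    benefit: np.ndarray,
    prices: np.ndarray,
    assignment: np.ndarray,
    owner: np.ndarray,
    eps: float,
) -> None:
    n_rows = benefit.shape[0]
    unassigned = list(range(n_rows))
    while unassigned:
        i = unassigned.pop()
        values = benefit[i] - prices
        j = int(np.argmax(values))
        best = values[j]
        values[j] = -np.inf
        second = values.max() if len(values) > 1 else best - eps
        prices[j] += best - second + eps
        prev = owner[j]
        if prev >= 0:
            assignment[prev] = -1
            unassigned.append(prev)
        owner[j] = i
        assignment[i] = j


def _term_matrices(pocket: PatchSet, ligand: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    n_a, n_b = len(pocket), len(ligand)
    pd = np.array(
        [[pdist(pa.descriptor, pb.descriptor) for pb in ligand.patches] for pa in pocket.patches]
    )
    ad = np.array(
        [[appd(pocket.app[i], ligand.app[j]) for j in range(n_b)] for i in range(n_a)]
    )
    return pd, ad


def _finite_geodesics(ps: PatchSet) -> np.ndarray:
    g = ps.geodesic
    if not np.all(np.isfinite(g)):
        warnings.warn(f"infinite geodesic capped at {GEODESIC_CAP} Å", stacklevel=3)
    return np.where(np.isfinite(g), g, GEODESIC_CAP)


def _match_sequential(
    pocket: PatchSet, ligand: PatchSet, w: DistanceWeights, pd: np.ndarray, ad: np.ndarray
) -> list[tuple[int, int]]:
    """Sequential auction: pairs are fixed one at a time; each new bid's grpd
    is evaluated against the pairs identified in the previous steps."""
    n_a, n_b = pd.shape
    g_a = _finite_geodesics(pocket)
    g_b = _finite_geodesics(ligand)
    base = w.w1 * pd + w.w2 * ad
    grpd_sum = np.zeros((n_a, n_b))
    free_a = np.ones(n_a, dtype=bool)
    free_b = np.ones(n_b, dtype=bool)
    pairs: list[tuple[int, int]] = []
    n_pairs = min(n_a, n_b)
    while len(pairs) < n_pairs:
        cost = base + (w.w3 * grpd_sum / len(pairs) if pairs else 0.0)
        cost = np.where(free_a[:, None] & free_b[None, :], cost, np.inf)
        i, j = np.unravel_index(int(np.argmin(cost)), cost.shape)
        pairs.append((int(i), int(j)))
        free_a[i] = False
        free_b[j] = False
        grpd_sum += np.abs(g_a[:, [i]] - g_b[[j], :])
    return sorted(pairs)


def _match_two_phase(
    pocket: PatchSet,
    ligand: PatchSet,
    w: DistanceWeights,
    pd: np.ndarray,
    ad: np.ndarray,
    max_rounds: int,
) -> list[tuple[int, int]]:
    """Iterated re-auction: solve with grpd = 0, then recompute full costs
    against the previous assignment and re-solve until stable."""
    n_a, n_b = pd.shape
    transpose = n_b <= n_a  # rows = smaller side for the auction
    pairs: list[tuple[int, int]] = []
    for _ in range(max_rounds):
        gd = np.zeros((n_a, n_b))
        if pairs:
            for i in range(n_a):
                for j in range(n_b):
                    gd[i, j] = grpd(i, j, pairs, pocket.geodesic, ligand.geodesic)
        full = w.w1 * pd + w.w2 * ad + w.w3 * gd
        if transpose:
            cols = auction_assign(full.T)  # rows = ligand patches
            new_pairs = sorted((int(cols[j]), j) for j in range(n_b))
        else:
            cols = auction_assign(full)
            new_pairs = sorted((i, int(cols[i])) for i in range(n_a))
        if new_pairs == pairs:
            break
        pairs = new_pairs
    return pairs


def match_patches(
    pocket: PatchSet,
    ligand: PatchSet,
    w: DistanceWeights = OPTIMIZED_WEIGHTS,
    algorithm: str = "sequential",
    max_rounds: int = 5,
) -> Matching:
    """Pocket/ligand patch correspondence under the three-term score.

    ``sequential`` (default) fixes pairs one at a time, lowest current cost
    first, scoring each candidate's grpd against the pairs already fixed —
    the grpd context grows as the search proceeds.  ``two_phase`` solves a
    full assignment with grpd ignored, then repeatedly re-solves with costs
    recomputed against the previous assignment (at most ``max_rounds``
    rounds).  Either way all patches of the smaller side are matched:
    N = min(n_A, n_B).
    """
    n_a, n_b = len(pocket), len(ligand)
    if n_a == 0 or n_b == 0:
        raise ValueError("cannot match empty patch sets")
    pd, ad = _term_matrices(pocket, ligand)
    if algorithm == "sequential":
        pairs = _match_sequential(pocket, ligand, w, pd, ad)
    elif algorithm == "two_phase":
        pairs = _match_two_phase(pocket, ligand, w, pd, ad, max_rounds)
    else:
        raise ValueError(f"unknown matching algorithm {algorithm!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gd_final = np.array(
            [grpd(i, j, pairs, pocket.geodesic, ligand.geodesic) for i, j in pairs]
        )
    return Matching(
        pairs,
        np.array([pd[i, j] for i, j in pairs]),
        np.array([ad[i, j] for i, j in pairs]),
        gd_final,
        w,
    )
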