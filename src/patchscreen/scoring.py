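"""Pocket-ligand complementarity scores, library ranking and PocketScore.

Given a patch matching, the overall fit of ligand B into pocket A is

    total_PL(A, B) = w1 * avgZd + w2 * avgGrpd + w3 * pocketSd

where avgZd averages the descriptor distance over matched pairs, avgGrpd
measures how consistently the matched patches are laid out on the two
surfaces (geodesic), and pocketSd penalises the pocket/ligand size
mismatch through the patch counts.  Lower totals mean better fits.

A pocket-similarity style variant uses a descriptor-only patch distance
for matching and the fixed combination

    total_PS(A, B) = 0.06 * avgZd + 0.14 * rdp + 0.8 * pocketSd

with rdp the Euclidean analogue of avgGrpd.

Library screening scores every conformer, averages each ligand's ten best
(lowest) conformer totals into a final score, and ranks ligands ascending.
For ligand-type prediction, PocketScore aggregates the top-k conformer
ranks per ligand type (k = 20), linearly weighted by rank and normalised
by the type's conformer count; the highest PocketScore wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import DistanceWeights, Matching, OPTIMIZED_WEIGHTS, PS_WEIGHTS, match_patches
from .patches import PatchSet

__all__ = [
    "TotalWeights",
    "TRAINED_TOTAL_WEIGHTS",
    "PS_TOTAL_WEIGHTS",
    "ScoreBreakdown",
    "ScreeningResult",
    "avg_zd",
    "avg_grpd",
    "pocket_sd",
    "totalscore_pl",
    "rdp",
    "totalscore_ps",
    "score_pair",
    "rank_library",
    "pocket_score",
]


@dataclass(frozen=True)
class TotalWeights:
    """Weights of (avgZd, avgGrpd-or-rdp, pocketSd) in a total score."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("total-score weights must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


#: Screening-trained weights for the pocket-ligand total score.
TRAINED_TOTAL_WEIGHTS = TotalWeights(0.8, 0.0, 0.1)
#: Fixed weights of the pocket-similarity style total score.
PS_TOTAL_WEIGHTS = TotalWeights(0.06, 0.14, 0.8)


@dataclass
class ScoreBreakdown:
    avg_zd: float
    avg_grpd: float
    pocket_sd: float
    total: float
    mode: str = "pl"
    conformer_id: str = ""


@dataclass
class ScreeningResult:
    """Ranked screening table plus the per-conformer score list."""

    table: pd.DataFrame  # ligand_id, final_score, rank, n_conformers_scored, active
    conformer_scores: pd.DataFrame  # ligand_id, conformer_id, total

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.table.sort_values("rank")["ligand_id"])


def avg_zd(m: Matching, n_pocket: int | None = None, coverage_penalty: bool = False) -> float:
    """Mean descriptor distance over matched pairs.

    With ``coverage_penalty`` the mean is additionally scaled by
    n_pocket / N, penalising matchings that cover few pocket patches.
    """
    if m.n_pairs == 0:
        raise ValueError("empty matching")
    mean = float(np.mean(m.pdist))
    if coverage_penalty:
        if n_pocket is None:
            raise ValueError("coverage penalty needs the pocket patch count")
        mean *= n_pocket / m.n_pairs
    return mean


def _relative_position_difference(m: Matching, mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    n = m.n_pairs
    if n < 2:
        warnings.warn("fewer than 2 matched pairs: relative-position term is 0", stacklevel=3)
        return 0.0
    pids, lids = m.pocket_ids(), m.ligand_ids()
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            da = mat_a[pids[i], pids[j]]
            db = mat_b[lids[i], lids[j]]
            da = da if np.isfinite(da) else 40.0
            db = db if np.isfinite(db) else 40.0
            total += abs(da - db)
    return 2.0 * total / (n * (n - 1))


def avg_grpd(m: Matching, g2_a: np.ndarray, g2_b: np.ndarray) -> float:
    """Geodesic relative-position difference averaged over matched couples."""
    return _relative_position_difference(m, g2_a, g2_b)


def rdp(m: Matching, l2_a: np.ndarray, l2_b: np.ndarray) -> float:
    """Euclidean relative-position difference averaged over matched couples."""
    return _relative_position_difference(m, l2_a, l2_b)


def pocket_sd(n_a: int, n_b: int) -> float:
    """Relative pocket/ligand size difference via patch counts, in [0, 1)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("patch counts must be positive")
    return abs(n_a - n_b) / max(n_a, n_b)


def totalscore_pl(
    avg_zd_val: float, avg_grpd_val: float, pocket_sd_val: float, w: TotalWeights = TRAINED_TOTAL_WEIGHTS
) -> float:
    """Pocket-ligand total score (lower is better)."""
    return w.w1 * avg_zd_val + w.w2 * avg_grpd_val + w.w3 * pocket_sd_val


def totalscore_ps(avg_zd_val: float, rdp_val: float, pocket_sd_val: float) -> float:
    """Pocket-similarity style total score with fixed 0.06/0.14/0.8 weights."""
    w = PS_TOTAL_WEIGHTS
    return w.w1 * avg_zd_val + w.w2 * rdp_val + w.w3 * pocket_sd_val


def score_pair(
    pocket: PatchSet,
    ligand: PatchSet,
    distance_weights: DistanceWeights = OPTIMIZED_WEIGHTS,
    total_weights: TotalWeights = TRAINED_TOTAL_WEIGHTS,
    mode: str = "pl",
    matching: Matching | None = None,
) -> ScoreBreakdown:
    """Match a pocket against one ligand conformer and score the fit."""
    if mode not in {"pl", "ps"}:
        raise ValueError("mode must be 'pl' or 'ps'")
    if matching is None:
        dw = distance_weights if mode == "pl" else PS_WEIGHTS
        matching = match_patches(pocket, ligand, dw)
    zd = avg_zd(matching)
    sd = pocket_sd(len(pocket), len(ligand))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mode == "pl":
            pos = avg_grpd(matching, pocket.geodesic, ligand.geodesic)
            total = totalscore_pl(zd, pos, sd, total_weights)
        else:
            pos = rdp(matching, pocket.euclidean, ligand.euclidean)
            total = totalscore_ps(zd, pos, sd)
    return ScoreBreakdown(zd, pos, sd, total, mode, ligand.source)


def rank_library(
    pocket: PatchSet,
    library: list[tuple[str, list[PatchSet]]],
    distance_weights: DistanceWeights = OPTIMIZED_WEIGHTS,
    total_weights: TotalWeights = TRAINED_TOTAL_WEIGHTS,
    mode: str = "pl",
    active_labels: dict[str, bool] | None = None,
    top_n_conformers: int = 10,
) -> ScreeningResult:
    """Rank a ligand library against a pocket.

    ``library`` maps each ligand id to the patch sets of its conformers.
    Each ligand's final score is the mean of its ``top_n_conformers``
    lowest conformer totals; ligands are ranked ascending, ties broken by
    ligand id.
    """
    if not library:
        raise ValueError("empty screening library")
    rows = []
    conf_rows = []
    for ligand_id, conformers in library:
        totals = []
        for k, ps in enumerate(conformers):
            if len(ps) == 0:
                warnings.warn(f"{ligand_id} conformer {k} has no patches; skipped", stacklevel=2)
                continue
            b = score_pair(pocket, ps, distance_weights, total_weights, mode)
            totals.append(b.total)
            conf_rows.append({"ligand_id": ligand_id, "conformer_id": k, "total": b.total})
        if not totals:
            warnings.warn(f"{ligand_id}: no scorable conformers; skipped", stacklevel=2)
            continue
        best = sorted(totals)[:top_n_conformers]
        rows.append(
            {
                "ligand_id": ligand_id,
                "final_score": float(np.mean(best)),
                "n_conformers_scored": len(best),
                "active": bool(active_labels.get(ligand_id, False)) if active_labels else False,
            }
        )
    table = pd.DataFrame(rows).sort_values(["final_score", "ligand_id"]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreeningResult(table, pd.DataFrame(conf_rows))


def pocket_score(
    ranked_conformers: list[tuple[str, float]],
    k: int = 20,
) -> dict[str, float]:
    """Ligand-type scores from a ranked conformer list.

    ``ranked_conformers`` is a list of (ligand_type, total_score) sorted or
    unsorted; conformers are ranked ascending by score.  Each type L gets
    sum over top-k ranks i of (k - i + 1) when the rank-i conformer is of
    type L, divided by the number of conformers of L in the database.  The
    type with the highest score is the predicted binder.
    """
    if not ranked_conformers:
        raise ValueError("empty conformer database")
    ordered = sorted(ranked_conformers, key=lambda t: (t[1], t[0]))
    counts: dict[str, int] = {}
    for label, _ in ordered:
        counts[label] = counts.get(label, 0) + 1
    k_eff = min(k, len(ordered))
    scores = {label: 0.0 for label in counts}
    for i, (label, _) in enumerate(ordered[:k_eff], start=1):
        scores[label] += k_eff - i + 1
    return {label: scores[label] / counts[label] for label in scores}
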