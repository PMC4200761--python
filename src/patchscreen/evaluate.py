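"""Evaluation machinery: native-contact recovery, weight searches, EF, AUC.

On a known complex, a pocket patch and a ligand patch form a native
contact when their centers lie within a cutoff (default 5.0 Å) in the
complex frame.  The maximum number of native contacts is the size of a
maximum one-to-one bipartite matching on the contact graph; the match
success rate divides the number of in-cutoff pairs a matching recovers by
that maximum, so it always lies in [0, 1].

Weight searches are exhaustive grids: the two-parameter (a, b) grid for
the patch-distance weights (w1, w2, w3) = (a*b, a*(1-b), 1-a), and the
full 11^3 grid for the total-score weights, scored by mean AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

from .matching import DistanceWeights, Matching
from .scoring import ScreeningResult, TotalWeights

__all__ = [
    "ContactMap",
    "EvalConfig",
    "max_native_contacts",
    "match_success_rate",
    "weight_grid",
    "optimize_distance_weights",
    "enrichment_factor",
    "roc_auc",
    "optimize_total_weights",
]


@dataclass
class ContactMap:
    """Pocket/ligand patch centers in the complex frame plus contact edges."""

    pocket_centers: np.ndarray
    ligand_centers: np.ndarray
    cutoff: float = 5.0
    contacts: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.pocket_centers = np.atleast_2d(np.asarray(self.pocket_centers, dtype=float))
        self.ligand_centers = np.atleast_2d(np.asarray(self.ligand_centers, dtype=float))
        d = np.linalg.norm(
            self.pocket_centers[:, None, :] - self.ligand_centers[None, :, :], axis=2
        )
        self.contacts = [(int(i), int(j)) for i, j in zip(*np.nonzero(d <= self.cutoff))]

    def in_contact(self, pocket_id: int, ligand_id: int) -> bool:
        return (
            np.linalg.norm(self.pocket_centers[pocket_id] - self.ligand_centers[ligand_id])
            <= self.cutoff
        )


@dataclass
class EvalConfig:
    cutoff: float = 5.0
    grid_step: float = 0.1
    ef_levels: tuple[float, ...] = (1.0, 10.0, 20.0)


def max_native_contacts(cm: ContactMap) -> int:
    """Maximum one-to-one pocket/ligand contact pairing (bipartite matching)."""
    if not cm.contacts:
        return 0
    g = nx.Graph()
    left = {f"p{i}" for i, _ in cm.contacts}
    g.add_nodes_from(left, bipartite=0)
    for i, j in cm.contacts:
        g.add_edge(f"p{i}", f"l{j}")
    matching = nx.bipartite.maximum_matching(g, top_nodes=left)
    return len(matching) // 2


def match_success_rate(m: Matching, cm: ContactMap) -> float:
    """Fraction of recoverable native contacts found by a matching."""
    denom = max_native_contacts(cm)
    if denom == 0:
        warnings.warn("no native contacts: success rate undefined", stacklevel=2)
        return float("nan")
    hits = sum(1 for i, j in m.pairs if cm.in_contact(i, j))
    return hits / denom


def weight_grid(
    a_range: tuple[float, float] = (0.0, 1.0),
    b_range: tuple[float, float] = (0.0, 1.0),
    step: float = 0.1,
) -> list[tuple[float, float, DistanceWeights]]:
    """All (a, b, weights) grid points with (w1,w2,w3) = (a*b, a*(1-b), 1-a)."""
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    n_a = round((a_range[1] - a_range[0]) / step)
    n_b = round((b_range[1] - b_range[0]) / step)
    out = []
    for i in range(n_a + 1):
        a = round(a_range[0] + i * step, 10)
        for j in range(n_b + 1):
            b = round(b_range[0] + j * step, 10)
            out.append((a, b, DistanceWeights.from_ab(a, b)))
    return out


def optimize_distance_weights(
    complexes: list,
    cfg: EvalConfig = EvalConfig(),
    match_fn=None,
) -> tuple[DistanceWeights, float, dict]:
    """Exhaustive (a, b) grid search of the patch-distance weights.

    ``complexes`` is a list of (pocket PatchSet, ligand PatchSet,
    ContactMap) triples.  Returns (best weights, best mean success rate,
    full table keyed by (a, b)); ties resolved toward smaller (a, b).
    """
    from .matching import match_patches

    matcher = match_fn or match_patches
    results: dict[tuple[float, float], float] = {}
    best_key, best_rate = None, -1.0
    for a, b, w in weight_grid(step=cfg.grid_step):
        rates = []
        for pocket, ligand, cm in complexes:
            m = matcher(pocket, ligand, w)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = match_success_rate(m, cm)
            if not math.isnan(r):
                rates.append(r)
        mean_rate = float(np.mean(rates)) if rates else 0.0
        results[(a, b)] = mean_rate
        if mean_rate > best_rate:  # grid iterates ascending (a, b): first max wins ties
            best_key, best_rate = (a, b), mean_rate
    return DistanceWeights.from_ab(*best_key), best_rate, results


def enrichment_factor(result: ScreeningResult, level_pct: float) -> float:
    """Active enrichment in the top X% of the ranked library.

    EF = (actives in top ceil(X% * n) / ceil(X% * n)) / (actives / n).
    """
    table = result.table.sort_values("rank")
    n = len(table)
    n_actives = int(table["active"].sum())
    if n == 0 or n_actives == 0:
        raise ValueError("enrichment factor needs at least one active and one compound")
    top = max(1, math.ceil(level_pct / 100.0 * n))
    hits = int(table.head(top)["active"].sum())
    return (hits / top) / (n_actives / n)


def roc_auc(result: ScreeningResult) -> float:
    """Probability that an active outranks (scores lower than) a decoy.

    Rank-based AUC with ties counted half; equivalent to the area under the
    ROC curve of the score-ordered library.
    """
    table = result.table
    actives = table[table["active"]]["final_score"].to_numpy()
    decoys = table[~table["active"]]["final_score"].to_numpy()
    if len(actives) == 0 or len(decoys) == 0:
        raise ValueError("AUC needs both actives and decoys")
    wins = (actives[:, None] < decoys[None, :]).sum()
    ties = (actives[:, None] == decoys[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(actives) * len(decoys)))


def optimize_total_weights(
    training_sets: list[list[tuple[str, bool, list[tuple[float, float, float]]]]],
    step: float = 0.1,
    top_n_conformers: int = 10,
) -> tuple[TotalWeights, float]:
    """Exhaustive grid search of total-score weights by mean training AUC.

    Each training set is a list of (ligand_id, active, conformer component
    triples (avgZd, avgGrpd, pocketSd)).  Components are precomputed once
    (the matching does not depend on the total-score weights), so each of
    the 11^3 candidate triples only re-ranks the library.  Ties resolve to
    the lexicographically smallest (w1, w2, w3).
    """
    import pandas as pd

    n_steps = round(1.0 / step)
    grid = [
        (round(i * step, 10), round(j * step, 10), round(k * step, 10))
        for i, j, k in product(range(n_steps + 1), repeat=3)
    ]
    best_w, best_auc = None, -1.0
    for w1, w2, w3 in grid:
        aucs = []
        for tset in training_sets:
            rows = []
            for ligand_id, active, comps in tset:
                totals = sorted(w1 * z + w2 * g + w3 * s for z, g, s in comps)
                rows.append(
                    {
                        "ligand_id": ligand_id,
                        "final_score": float(np.mean(totals[:top_n_conformers])),
                        "active": active,
                    }
                )
            table = pd.DataFrame(rows).sort_values(["final_score", "ligand_id"]).reset_index(drop=True)
            table["rank"] = np.arange(1, len(table) + 1)
            aucs.append(roc_auc(ScreeningResult(table, pd.DataFrame())))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_w, best_auc = (w1, w2, w3), mean_auc
    return TotalWeights(*best_w), best_auc
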