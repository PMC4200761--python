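"""Native contacts, weight grids, enrichment factors and ROC AUC."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from patchscreen.evaluate import (
    ContactMap,
    EvalConfig,
    enrichment_factor,
    match_success_rate,
    max_native_contacts,
    optimize_distance_weights,
    optimize_total_weights,
    roc_auc,
    weight_grid,
)
from patchscreen.matching import DistanceWeights, Matching
from patchscreen.scoring import ScreeningResult


def _result(scores_actives, scores_decoys):
    rows = [{"ligand_id": f"a{i}", "final_score": s, "active": True} for i, s in enumerate(scores_actives)]
    rows += [{"ligand_id": f"d{i}", "final_score": s, "active": False} for i, s in enumerate(scores_decoys)]
    table = pd.DataFrame(rows).sort_values(["final_score", "ligand_id"]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreeningResult(table, pd.DataFrame())


def _matching(pairs):
    n = len(pairs)
    return Matching(pairs, np.zeros(n), np.zeros(n), np.zeros(n), DistanceWeights(1, 0, 0))


def _brute_force_max_matching(contacts, n_p, n_l):
    best = 0
    for k in range(min(n_p, n_l), 0, -1):
        from itertools import combinations

        for ps in combinations(range(n_p), k):
            for perm in permutations(range(n_l), k):
                if all((p, l) in contacts for p, l in zip(ps, perm)):
                    return k
    return best


class TestNativeContacts:
    def test_full_bipartite_square(self):
        cm = ContactMap(np.zeros((2, 3)), np.ones((2, 3)) * 0.1, cutoff=5.0)
        assert len(cm.contacts) == 4
        assert max_native_contacts(cm) == 2

    def test_no_contacts(self):
        cm = ContactMap(np.zeros((2, 3)), np.ones((2, 3)) * 100, cutoff=5.0)
        assert max_native_contacts(cm) == 0

    def test_one_ligand_patch_near_three_protein_patches(self):
        protein = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        ligand = np.array([[1, 1, 0]], dtype=float)
        cm = ContactMap(protein, ligand, cutoff=5.0)
        assert max_native_contacts(cm) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_against_exhaustive_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_p, n_l = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        protein = rng.random((n_p, 3)) * 6
        ligand = rng.random((n_l, 3)) * 6
        cm = ContactMap(protein, ligand, cutoff=3.0)
        assert max_native_contacts(cm) == _brute_force_max_matching(set(cm.contacts), n_p, n_l)


class TestSuccessRate:
    def test_perfect_recovery(self):
        protein = np.array([[0, 0, 0], [4, 0, 0]], dtype=float)
        ligand = protein + [0, 1, 0]
        cm = ContactMap(protein, ligand, cutoff=5.0)
        assert match_success_rate(_matching([(0, 0), (1, 1)]), cm) == 1.0

    def test_half_recovery(self):
        protein = np.array([[0, 0, 0], [40, 0, 0]], dtype=float)
        ligand = np.array([[0, 1, 0], [40, 1, 0]], dtype=float)
        cm = ContactMap(protein, ligand, cutoff=5.0)
        assert match_success_rate(_matching([(0, 0), (1, 0)]), cm) == pytest.approx(0.5)

    def test_disjoint_matching_scores_zero(self):
        protein = np.array([[0, 0, 0], [40, 0, 0]], dtype=float)
        ligand = np.array([[0, 1, 0], [40, 1, 0]], dtype=float)
        cm = ContactMap(protein, ligand, cutoff=5.0)
        assert match_success_rate(_matching([(0, 1), (1, 0)]), cm) == 0.0

    def test_rate_bounded_by_one(self, small_complex):
        from patchscreen.matching import match_patches

        m = match_patches(small_complex.pocket_patches, small_complex.ligand_patches)
        r = match_success_rate(m, small_complex.contact_map)
        assert 0.0 <= r <= 1.0

    def test_undefined_without_contacts(self):
        cm = ContactMap(np.zeros((1, 3)), np.full((1, 3), 99.0), cutoff=5.0)
        with pytest.warns(UserWarning):
            assert math.isnan(match_success_rate(_matching([(0, 0)]), cm))


class TestWeightGrid:
    def test_grid_size_and_normalization(self):
        grid = weight_grid(step=0.1)
        assert len(grid) == 121
        for _, _, w in grid:
            assert w.w1 + w.w2 + w.w3 == pytest.approx(1.0)

    def test_published_rows_are_grid_points(self):
        grid = {(round(a, 2), round(b, 2)): w for a, b, w in weight_grid(step=0.1)}
        assert grid[(0.5, 0.7)].as_tuple() == pytest.approx((0.35, 0.15, 0.5))
        assert grid[(0.8, 0.4)].as_tuple() == pytest.approx((0.32, 0.48, 0.2))

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            weight_grid(step=0.0)


class TestOptimizeDistanceWeights:
    def test_unique_winner_recovered(self):
        # fake matcher: success only when w is (close to) the planted triple
        planted = DistanceWeights.from_ab(0.5, 0.7)
        protein = np.array([[0, 0, 0]], dtype=float)
        ligand = np.array([[0, 1, 0]], dtype=float)
        cm = ContactMap(protein, ligand, cutoff=5.0)

        # an empty matching scores 0 hits; only the planted triple scores 1
        def matcher(pocket, lig, w):
            if np.allclose(w.as_tuple(), planted.as_tuple(), atol=1e-9):
                return _matching([(0, 0)])
            return Matching([], np.zeros(0), np.zeros(0), np.zeros(0), w)

        best, rate, table = optimize_distance_weights([(None, None, cm)], match_fn=matcher)
        assert best.as_tuple() == pytest.approx(planted.as_tuple())
        assert rate == 1.0
        assert rate == max(table.values())

    def test_tie_breaks_to_smallest_ab(self):
        cm = ContactMap(np.zeros((1, 3)), np.array([[0, 1, 0.0]]), cutoff=5.0)

        def matcher(pocket, lig, w):
            return _matching([(0, 0)])  # every triple succeeds equally

        best, rate, table = optimize_distance_weights([(None, None, cm)], match_fn=matcher)
        assert best.as_tuple() == pytest.approx(DistanceWeights.from_ab(0.0, 0.0).as_tuple())


class TestEnrichment:
    def test_perfect_early_enrichment(self):
        res = _result([0.1] * 10, [0.9] * 90)
        assert enrichment_factor(res, 10.0) == pytest.approx(10.0)

    def test_no_actives_in_top(self):
        res = _result([0.9] * 10, [0.1] * 90)
        assert enrichment_factor(res, 10.0) == 0.0

    def test_full_list_enrichment_is_one(self):
        res = _result([0.4, 0.8], [0.1, 0.5, 0.9])
        assert enrichment_factor(res, 100.0) == pytest.approx(1.0)

    def test_random_ranking_enrichment_near_one(self):
        rng = np.random.default_rng(0)
        efs = []
        for _ in range(1000):
            scores = rng.permutation(100)
            res = _result(scores[:10], scores[10:])
            efs.append(enrichment_factor(res, 20.0))
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)

    def test_no_actives_rejected(self):
        res = _result([], [0.1, 0.2])
        with pytest.raises(ValueError):
            enrichment_factor(res, 10.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(_result([0.1, 0.2], [0.5, 0.6])) == 1.0

    def test_inverted_separation(self):
        assert roc_auc(_result([0.9, 0.8], [0.1, 0.2])) == 0.0

    def test_all_tied_scores(self):
        assert roc_auc(_result([0.5, 0.5], [0.5, 0.5])) == 0.5

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        actives = rng.random(8)
        decoys = rng.random(15)
        res = _result(actives, decoys)
        labels = [1] * 8 + [0] * 15
        # lower score = better: negate for sklearn's higher-is-positive convention
        expected = roc_auc_score(labels, -np.concatenate([actives, decoys]))
        assert roc_auc(res) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_result([0.1], []))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        actives, decoys = rng.random(6), rng.random(9)
        a = roc_auc(_result(actives, decoys))
        b = roc_auc(_result(np.exp(actives * 3), np.exp(decoys * 3)))
        assert a == pytest.approx(b)


class TestOptimizeTotalWeights:
    def test_grid_is_exhaustive(self):
        # single target where only a pure-avgZd score ranks the active first
        tset = [
            ("act", True, [(0.1, 9.0, 9.0)]),
            ("dec", False, [(0.9, 0.1, 0.1)]),
        ]
        best, auc = optimize_total_weights([tset], step=0.5)
        assert auc == 1.0
        assert best.w1 > 0 and best.w2 == 0.0 and best.w3 == 0.0

    def test_grid_size(self):
        from itertools import product

        n = sum(1 for _ in product(range(11), repeat=3))
        assert n == 1331  # the 0.1-step grid enumerated by the optimizer

    def test_returned_auc_is_grid_maximum(self):
        rng = np.random.default_rng(2)
        tset = [
            (f"l{i}", bool(i % 2), [tuple(rng.random(3)) for _ in range(3)])
            for i in range(8)
        ]
        best, auc = optimize_total_weights([tset], step=0.25)
        # re-evaluate the winning triple by hand
        rows = []
        for lid, active, comps in tset:
            totals = sorted(best.w1 * z + best.w2 * g + best.w3 * s for z, g, s in comps)
            rows.append({"ligand_id": lid, "final_score": np.mean(totals[:10]), "active": active})
        table = pd.DataFrame(rows).sort_values(["final_score", "ligand_id"]).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        assert roc_auc(ScreeningResult(table, pd.DataFrame())) == pytest.approx(auc)
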