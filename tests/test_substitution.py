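"""Pricing, candidate search, trade-off selection, frontier, transitions."""

import numpy as np
import pandas as pd
import pytest

from mealforge.portioning import MealTargets, RDITable, per_meal_targets
from mealforge.substitution import (
    PricingModel,
    SubstitutionCandidate,
    TradeoffPolicy,
    find_candidates,
    frontier,
    hop_count,
    knee_point,
    meal_cost,
    nutrition_gain,
    select,
    transition_matrix,
)
from tests.conftest import corpus_from_items, tiny_catalog
from mealforge.nutrients import ENERGY


@pytest.fixture()
def pricing():
    return PricingModel(
        categories={
            "grains": {"grams_per_portion": 60.0, "price_per_portion": 2.0, "item_cap": 3.0},
            "soups": {"grams_per_portion": 240.0, "price_per_portion": 4.0, "item_cap": 1.0},
        },
        cross_item_caps={"soups": 1.0},
    )


@pytest.fixture()
def cat():
    return tiny_catalog(
        [
            {"code": "G1", "main_category": "grains", ENERGY: 2.0, "protein": 0.08,
             "carbohydrate": 0.4, "fat": 0.02, "fiber": 0.03},
            {"code": "G2", "main_category": "grains", ENERGY: 2.2, "protein": 0.1,
             "carbohydrate": 0.42, "fat": 0.03, "fiber": 0.05},
            {"code": "V1", "main_category": "vegetables", ENERGY: 0.4, "protein": 0.02,
             "carbohydrate": 0.06, "fiber": 0.03, "vitamin_c": 0.3},
            {"code": "S1", "main_category": "soups", ENERGY: 0.5, "protein": 0.03,
             "carbohydrate": 0.05, "sodium": 2.0},
            {"code": "P1", "main_category": "protein_foods", ENERGY: 1.9, "protein": 0.2,
             "fat": 0.1, "iron": 0.01},
        ]
    )


class TestMealCost:
    def test_generic_default_single_portion(self, cat):
        pm = PricingModel()
        # 150 g of an unpriced category: one generic portion (3) + overhead (2)
        assert meal_cost([("V1", 150.0)], cat, pm) == pytest.approx(5.0)

    def test_empty_meal_costs_overhead_only(self, cat, pricing):
        assert meal_cost([], cat, pricing) == pytest.approx(2.0)

    def test_soup_cross_item_cap_bills_one_bowl(self, cat, pricing):
        items = [("S1", 240.0)] * 1 + [("S1", 240.0), ("S1", 240.0)]
        # identical codes would violate the corpus invariant, but cost is
        # computed per item line; three bowls bill as one
        cost = meal_cost(items, cat, pricing)
        assert cost == pytest.approx(2.0 + 1.0 * 4.0)

    def test_per_item_cap(self, cat, pricing):
        # 60 g/portion with cap 3: 600 g bills 3 portions, not 10
        assert meal_cost([("G1", 600.0)], cat, pricing) == pytest.approx(2.0 + 3 * 2.0)

    def test_negative_grams_rejected(self, cat, pricing):
        with pytest.raises(ValueError, match="negative"):
            meal_cost([("G1", -5.0)], cat, pricing)

    def test_monotone_in_grams(self, cat, pricing):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.uniform(10, 500)
            extra = rng.uniform(1, 100)
            a = meal_cost([("G1", g), ("S1", 100.0)], cat, pricing)
            b = meal_cost([("G1", g + extra), ("S1", 100.0)], cat, pricing)
            assert b >= a - 1e-12

    def test_per100g_dialect(self, cat):
        pm = PricingModel(
            categories={"grains": {"grams_per_portion": 60.0, "price_per_portion": 2.0,
                                   "price_per_100g": 1.5}},
            dialect="per100g", overhead=2.0,
        )
        assert meal_cost([("G1", 200.0)], cat, pm) == pytest.approx(2.0 + 3.0)


class TestHopCount:
    @pytest.mark.parametrize(
        "a, b, k",
        [
            ({"A", "B"}, {"A", "B"}, 0),
            ({"A", "B", "C"}, {"A", "B", "D"}, 1),
            ({"A", "B"}, {"A", "C", "D"}, 2),  # one replace + one add
            ({"A", "B", "C"}, {"A"}, 2),
            (set("ABCD"), set("EFGH"), 4),
        ],
    )
    def test_max_of_set_differences(self, a, b, k):
        assert hop_count(a, b) == k


class TestNutritionGain:
    def targets(self):
        return MealTargets(
            "lunch", 0.35, {"protein": 20.0, "fiber": 8.0, "vitamin_c": 20.0,
                            "iron": 3.0}, {"sodium": 800.0}, 700.0,
        )

    def test_identity_candidate_zero_gain(self, cat):
        items = [("G1", 100.0), ("V1", 100.0)]
        assert nutrition_gain(items, items, cat, self.targets()) == pytest.approx(0.0)

    def test_halved_deviation_fifty_percent(self, cat):
        t = MealTargets("lunch", 0.35, {"protein": 20.0}, {}, 700.0)
        orig = [("P1", 50.0)]  # protein 10, deviation 0.5
        cand = [("P1", 75.0)]  # protein 15, deviation 0.25
        assert nutrition_gain(orig, cand, cat, t) == pytest.approx(50.0)

    def test_zero_original_deviation_undefined(self, cat):
        t = MealTargets("lunch", 0.35, {"protein": 20.0}, {}, 700.0)
        orig = [("P1", 100.0)]  # exactly at target
        assert nutrition_gain(orig, [("P1", 50.0)], cat, t) is None


def _mk_candidate(gain, cost, cost_delta, k, source="real:x"):
    return SubstitutionCandidate(items=[], source=source, k=k, gain_pct=gain,
                                 cost=cost, cost_delta=cost_delta)


class TestSelect:
    def test_theta_zero_pure_nutrition_argmax(self):
        cands = [_mk_candidate(5, 10, 1, 1), _mk_candidate(9, 20, 11, 2),
                 _mk_candidate(7, 5, -4, 1)]
        w = select(cands, TradeoffPolicy(theta=0.0), original_cost=9.0)
        assert w.gain_pct == 9

    def test_no_cost_increase_filter(self):
        cands = [_mk_candidate(9, 20, 11, 2), _mk_candidate(7, 5, -4, 1)]
        w = select(cands, TradeoffPolicy(theta=0.0, no_cost_increase=True), 9.0)
        assert w.cost_delta <= 0

    def test_budget_filter(self):
        cands = [_mk_candidate(9, 20, 11, 2), _mk_candidate(7, 5, -4, 1)]
        w = select(cands, TradeoffPolicy(theta=0.0, budget=10.0), 9.0)
        assert w.cost <= 10.0

    def test_matches_brute_force_score(self):
        rng = np.random.default_rng(1)
        policy = TradeoffPolicy(theta=1.0)
        cands = [
            _mk_candidate(rng.uniform(-5, 15), rng.uniform(2, 20), rng.uniform(-5, 5),
                          int(rng.integers(1, 4)), source=f"real:{i}")
            for i in range(5)
        ]
        cost0 = 10.0
        w = select(cands, policy, cost0)
        scores = [c.gain_pct + 1.0 * 100.0 * (cost0 - c.cost) / cost0 for c in cands]
        assert w.gain_pct + 100.0 * (cost0 - w.cost) / cost0 == pytest.approx(max(scores))

    def test_empty_pool_returns_none(self):
        assert select([], TradeoffPolicy(theta=0.0), 5.0) is None
        cands = [_mk_candidate(5, 20, 10, 1)]
        assert select(cands, TradeoffPolicy(theta=0, no_cost_increase=True), 5.0) is None


class TestFindCandidates:
    def _real(self):
        return corpus_from_items(
            [
                ("R1", "lunch", [("G1", 100.0), ("V1", 120.0)]),
                ("R2", "lunch", [("G1", 100.0), ("P1", 110.0)]),
                ("R3", "lunch", [("G2", 90.0), ("V1", 100.0), ("P1", 60.0)]),
                ("R4", "lunch", [("S1", 400.0)]),
                ("R5", "dinner", [("G1", 100.0), ("V1", 120.0)]),
            ]
        )

    def test_identity_excluded_and_one_hop_found(self, cat, pricing):
        t = per_meal_targets(RDITable(), "lunch")
        gen = [("G1", 100.0), ("V1", 120.0)]
        out = find_candidates(gen, "lunch", self._real(), cat, t, pricing,
                              energy_tol=5.0, count_tol=1, include_swaps=False)
        sources = {c.source for c in out}
        assert "real:R1" not in sources  # k = 0 identity
        assert "real:R2" in sources
        k_by_source = {c.source: c.k for c in out}
        assert k_by_source["real:R2"] == 1

    def test_meal_type_respected(self, cat, pricing):
        t = per_meal_targets(RDITable(), "lunch")
        gen = [("G1", 100.0), ("V1", 120.0)]
        out = find_candidates(gen, "lunch", self._real(), cat, t, pricing,
                              energy_tol=5.0, include_swaps=False)
        assert all(c.source != "real:R5" for c in out)

    def test_matches_exhaustive_filter(self, cat, pricing):
        """Candidate set equals a brute-force filter over all real meals."""
        t = per_meal_targets(RDITable(), "lunch")
        gen = [("G1", 100.0), ("V1", 120.0)]
        energy_tol, count_tol = 0.5, 1
        out = find_candidates(gen, "lunch", self._real(), cat, t, pricing,
                              energy_tol=energy_tol, count_tol=count_tol,
                              include_swaps=False)
        got = {c.source for c in out}
        # independent brute force
        e = lambda items: sum(g * cat.df.loc[f, ENERGY] for f, g in items)
        gen_e = e(gen)
        expected = set()
        real = self._real()
        for mid in real.by_meal_type("lunch").meal_ids:
            items = real.items(mid)
            k = hop_count({f for f, _ in gen}, {f for f, _ in items})
            if (k >= 1 and abs(len(items) - len(gen)) <= count_tol
                    and abs(e(items) - gen_e) / gen_e <= energy_tol):
                expected.add(f"real:{mid}")
        assert got == expected

    def test_single_item_swaps_transfer_grams(self, cat, pricing):
        t = per_meal_targets(RDITable(), "lunch")
        gen = [("G1", 100.0), ("V1", 120.0)]
        out = find_candidates(gen, "lunch", self._real(), cat, t, pricing,
                              energy_tol=5.0, include_swaps=True)
        swaps = [c for c in out if c.source.startswith("swap:")]
        assert swaps, "same-category swap G1->G2 expected"
        for c in swaps:
            assert c.k == 1
            assert sorted(g for _, g in c.items) == sorted(g for _, g in gen)

    def test_gain_cost_self_consistent(self, cat, pricing):
        """Recomputing winner gain/cost from raw meals reproduces stored values."""
        t = per_meal_targets(RDITable(), "lunch")
        gen = [("G1", 100.0), ("V1", 120.0)]
        out = find_candidates(gen, "lunch", self._real(), cat, t, pricing, energy_tol=5.0)
        assert out
        for c in out:
            assert c.cost == pytest.approx(meal_cost(c.items, cat, pricing), abs=1e-9)
            g = nutrition_gain(gen, c.items, cat, t)
            assert g == pytest.approx(c.gain_pct, abs=1e-9)


class TestFrontierAndTransitions:
    def test_knee_geometry_oracle(self):
        # constructed curve: knee at the sharpest bend, found by brute force
        s = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        g = np.array([0.0, 5.0, 9.0, 10.0, 10.5])
        idx = knee_point(s, g)
        pts = np.stack([s, g], 1)
        a, b = pts[0], pts[-1]
        chord = (b - a) / np.linalg.norm(b - a)
        d = [abs(chord[0] * (p - a)[1] - chord[1] * (p - a)[0]) for p in pts]
        assert idx == int(np.argmax(d))

    def test_single_theta_degenerate_curve(self, cat, pricing):
        real = corpus_from_items(
            [
                ("R1", "lunch", [("G1", 100.0), ("V1", 120.0)]),
                ("R2", "lunch", [("G1", 100.0), ("P1", 110.0)]),
            ]
        )
        t = {mt: per_meal_targets(RDITable(), mt) for mt in ("breakfast", "lunch", "dinner")}
        gen = [([("G1", 110.0), ("V1", 100.0)], "lunch")]
        out = frontier(gen, real, cat, t, pricing, theta_grid=[0.5], n_boot=50,
                       energy_tol=5.0)
        assert len(out["curve"]) == 1
        assert out["feasibility_fraction"] == 1.0
        assert "knee" in out and out["knee"]["theta"] == 0.5

    def test_feasibility_fraction_counts(self, cat, pricing):
        real = corpus_from_items([("R1", "lunch", [("G1", 100.0), ("V1", 120.0)])])
        t = {mt: per_meal_targets(RDITable(), mt) for mt in ("breakfast", "lunch", "dinner")}
        gen = [
            ([("G2", 110.0), ("V1", 100.0)], "lunch"),  # one hop from R1
            ([("P1", 400.0)], "dinner"),  # no dinner meals -> infeasible
        ]
        out = frontier(gen, real, cat, t, pricing, theta_grid=[0.0], n_boot=50,
                       energy_tol=5.0, include_swaps=False)
        assert out["feasibility_fraction"] == 0.5

    def test_transition_matrix_counting(self, cat):
        orig = [("G1", 100.0), ("V1", 100.0)]
        winner = SubstitutionCandidate(
            items=[("G1", 100.0), ("P1", 100.0)], source="real:R2", k=1
        )
        mat, marg = transition_matrix([(orig, winner)] * 10, cat)
        assert mat.loc["vegetables", "protein_foods"] == pytest.approx(1.0)
        assert np.allclose(mat.sum(axis=1)[mat.sum(axis=1) > 0], 1.0)

    def test_transition_rows_normalised_mixed(self, cat):
        pairs = []
        for add in ("P1", "G2"):
            orig = [("V1", 50.0), ("S1", 100.0)]
            winner = SubstitutionCandidate(
                items=[("V1", 50.0), (add, 100.0)], source="x", k=1
            )
            pairs.append((orig, winner))
        mat, _ = transition_matrix(pairs, cat)
        row = mat.loc["soups"]
        assert row.sum() == pytest.approx(1.0)
        assert row["protein_foods"] == pytest.approx(0.5)
        assert row["grains"] == pytest.approx(0.5)

    def test_no_swaps_raises(self, cat):
        orig = [("G1", 100.0)]
        winner = SubstitutionCandidate(items=[("G1", 100.0)], source="real:R9", k=0)
        with pytest.raises(ValueError, match="swap"):
            transition_matrix([(orig, winner)], cat)
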