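"""Selection algorithms against exhaustive subset-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from hlacover.optimize import (
    InfeasibleError,
    evaluate_coverage,
    greedy_cost_select,
    greedy_select,
    random_baseline,
    solve_ilp,
    solve_lp,
    target_weight,
)
from hlacover.scenarios import Scenario2Config
from tests.conftest import make_cov, toy_patients


def brute_force_min_cost(sets, weights, P, costs=None):
    """Cheapest subset whose union weight reaches P, by full enumeration."""
    n = len(sets)
    costs = costs or [1.0] * n
    best = math.inf
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            covered = set().union(*(sets[j] for j in combo)) if combo else set()
            if sum(weights[i] for i in covered) >= P:
                best = min(best, sum(costs[j] for j in combo))
    return best


def brute_force_opt_k(sets, weights, k):
    """Max covered weight achievable with exactly <= k sets (OPT(k))."""
    best = 0
    for combo in itertools.combinations(range(len(sets)), min(k, len(sets))):
        covered = set().union(*(sets[j] for j in combo)) if combo else set()
        best = max(best, sum(weights[i] for i in covered))
    return best


def random_instance(rng, n_donors=None, n_patients=None):
    n_d = n_donors or int(rng.integers(4, 13))
    n_p = n_patients or int(rng.integers(4, 16))
    weights = [int(w) for w in rng.integers(1, 10, size=n_p)]
    sets = []
    for _ in range(n_d):
        size = int(rng.integers(1, max(2, n_p // 2 + 1)))
        sets.append(set(int(i) for i in rng.choice(n_p, size=size, replace=False)))
    # guarantee full coverage is possible
    sets[0] |= set(range(n_p)) - set().union(*sets)
    return sets, weights


class TestGreedySelect:
    def test_single_donor_covers_all(self):
        cov = make_cov([{0, 1, 2}])
        patients = toy_patients([1, 1, 1])
        res = greedy_select(cov, patients, 1.0)
        assert res.selected == ("D0",)
        assert res.coverage_fraction == 1.0

    def test_three_set_instance_optimal_order(self):
        # S_A={1,2}, S_B={2,3}, S_C={3}: full cover needs A then B
        cov = make_cov([{0, 1}, {1, 2}, {2}])
        patients = toy_patients([1, 1, 1])
        res = greedy_select(cov, patients, 1.0)
        assert res.selected == ("D0", "D1")

    def test_tie_breaks_toward_lowest_index(self):
        cov = make_cov([{0, 1}, {0, 1}, {2}])
        res = greedy_select(cov, toy_patients([1, 1, 1]), 0.5)
        assert res.selected == ("D0",)

    def test_best_effort_flag_when_target_unreachable(self):
        cov = make_cov([{0}])
        res = greedy_select(cov, toy_patients([1, 1]), 1.0)
        assert not res.feasible
        assert res.coverage_fraction == 0.5

    def test_approximation_guarantee_at_fixed_budget(self, rng):
        """Truncated greedy reaches >= (1 - 1/e) * OPT(k)."""
        bound = 1 - 1 / math.e
        for _ in range(25):
            sets, weights = random_instance(rng)
            cov = make_cov(sets)
            patients = toy_patients(weights)
            full = greedy_select(cov, patients, 1.0)
            for k in (1, 2, 3):
                opt_k = brute_force_opt_k(sets, weights, k)
                greedy_k = sum(
                    it["added_weight"] for it in full.iterations[:k]
                )
                assert greedy_k >= bound * opt_k - 1e-9

    def test_priority_prefers_four_match_donor(self):
        # D0 covers patient 0 at 3 matches, D1 covers patient 1 at 4 matches;
        # equal weights: prior4 tips the choice to D1
        cov = make_cov(
            [{0}, {1}],
            match_counts=[{0: 3}, {1: 4}],
        )
        patients = toy_patients([1, 1])
        plain = greedy_select(cov, patients, 0.5)
        assert plain.selected == ("D0",)  # tie -> lowest index
        prio = greedy_select(
            cov, patients, 0.5, priority=Scenario2Config(prior4=10.0)
        )
        assert prio.selected == ("D1",)
        assert prio.tallies["weight_4_matches"] == 1


class TestLpIlp:
    def test_half_target_single_donor_lp(self):
        cov = make_cov([{0, 1}])
        lp = solve_lp(cov, toy_patients([1, 1]), 0.5)
        assert lp.objective == pytest.approx(0.5, abs=1e-6)

    def test_classic_integrality_gap_instance(self):
        # elements {0,1,2}; sets {0,1},{1,2},{0,2}: LP 1.5 vs ILP 2
        cov = make_cov([{0, 1}, {1, 2}, {0, 2}])
        patients = toy_patients([1, 1, 1])
        lp = solve_lp(cov, patients, 1.0)
        ilp = solve_ilp(cov, patients, 1.0)
        assert lp.objective == pytest.approx(1.5, abs=1e-6)
        assert ilp.objective == pytest.approx(2.0)
        assert len(ilp.selected) == 2

    def test_ilp_equals_brute_force_and_chain_holds(self, rng):
        for _ in range(50):
            sets, weights = random_instance(rng)
            cov = make_cov(sets)
            patients = toy_patients(weights)
            target = float(rng.choice([0.4, 0.6, 0.8, 1.0]))
            P = target_weight(patients, target)
            expected = brute_force_min_cost(sets, weights, P)
            lp = solve_lp(cov, patients, target)
            ilp = solve_ilp(cov, patients, target)
            greedy = greedy_select(cov, patients, target)
            assert ilp.objective == pytest.approx(expected)
            assert lp.objective <= ilp.objective + 1e-6
            assert ilp.objective <= greedy.objective + 1e-9
            assert greedy.covered_weight >= P

    def test_infeasible_reports_max_achievable(self):
        cov = make_cov([{0}])
        with pytest.raises(InfeasibleError) as exc:
            solve_ilp(cov, toy_patients([1, 3]), 1.0)
        assert exc.value.achievable == 1

    def test_ilp_with_heterogeneous_costs(self, rng):
        for _ in range(10):
            sets, weights = random_instance(rng, n_donors=8)
            costs = [float(c) for c in rng.integers(1, 12, size=len(sets))]
            cov = make_cov(sets, costs=costs)
            patients = toy_patients(weights)
            P = target_weight(patients, 0.7)
            expected = brute_force_min_cost(sets, weights, P, costs)
            ilp = solve_ilp(cov, patients, 0.7)
            assert ilp.objective == pytest.approx(expected)


class TestGreedyCostSelect:
    def _cov(self, full_sets, ko_sets, cost_ko=10.0):
        sets = full_sets + ko_sets
        knockout = [False] * len(full_sets) + [True] * len(ko_sets)
        costs = [1.0] * len(full_sets) + [cost_ko + 1.0] * len(ko_sets)
        return make_cov(sets, costs=costs, knockout=knockout)

    def test_single_full_donor_wins(self):
        cov = self._cov([{0, 1, 2}], [{0}])
        res = greedy_cost_select(cov, toy_patients([1, 1, 1]), 1.0)
        assert res.objective == 1.0
        assert res.tallies["n_knockouts"] == 0

    def test_knockout_forced_when_only_route(self):
        cov = self._cov([{0}], [{1}])
        res = greedy_cost_select(cov, toy_patients([1, 1]), 1.0)
        assert res.tallies["n_knockouts"] == 1
        assert res.objective == 12.0

    def test_decision_rule_arithmetic(self):
        # knockout covers 30 patients (11/30 per patient) vs 2 fulls covering
        # 4 (2/4 per patient): knockout is cheaper per patient and is chosen
        ko_set = set(range(2, 32))
        cov = self._cov([{0, 1}, {0, 1}], [ko_set])
        patients = toy_patients([1] * 32)
        res = greedy_cost_select(cov, patients, 30 / 32)
        assert res.iterations[0]["chose_knockout"]
        assert res.selected[0] == "D2"

    def test_full_preferred_when_cheaper_per_patient(self):
        # knockout covers 5 (11/5 = 2.2 each) vs one full covering 5 (0.2)
        cov = self._cov([{0, 1, 2, 3, 4}], [{0, 1, 2, 3, 4}])
        res = greedy_cost_select(cov, toy_patients([1] * 5), 1.0)
        assert res.tallies["n_knockouts"] == 0
        assert res.objective == 1.0


class TestRandomBaseline:
    def test_single_donor_pool_sd_zero(self):
        cov = make_cov([{0, 1}])
        res = random_baseline(cov, toy_patients([1, 1]), 1.0, seed=3)
        assert res.trials == 5
        assert res.donors_needed == [1] * 5
        assert res.sd == 0.0

    def test_deterministic_per_seed(self, rng):
        sets, weights = random_instance(rng, n_donors=10)
        cov = make_cov(sets)
        patients = toy_patients(weights)
        r1 = random_baseline(cov, patients, 0.8, seed=42)
        r2 = random_baseline(cov, patients, 0.8, seed=42)
        assert r1.donors_needed == r2.donors_needed

    def test_random_needs_at_least_greedy(self, rng):
        for _ in range(20):
            sets, weights = random_instance(rng)
            cov = make_cov(sets)
            patients = toy_patients(weights)
            greedy = greedy_select(cov, patients, 0.8)
            rand = random_baseline(cov, patients, 0.8, seed=int(rng.integers(1e6)))
            assert rand.mean >= len(greedy.selected)

    def test_full_only_excludes_knockouts(self):
        cov = make_cov(
            [{0}, {0, 1}],
            costs=[1.0, 11.0],
            knockout=[False, True],
        )
        res = random_baseline(cov, toy_patients([1, 1]), 1.0, seed=1, full_only=True)
        assert not res.feasible  # knockout was the only way to cover patient 1


class TestEvaluateCoverage:
    def test_empty_selection(self):
        cov = make_cov([{0, 1}])
        res = evaluate_coverage([], cov, toy_patients([2, 3]))
        assert res.covered_weight == 0
        assert res.objective == 0.0

    def test_union_semantics_overlap_counted_once(self):
        cov = make_cov([{0, 1}, {0, 1}])
        res = evaluate_coverage(["D0", "D1"], cov, toy_patients([2, 3]))
        assert res.covered_weight == 5
        one = evaluate_coverage(["D0"], cov, toy_patients([2, 3]))
        assert one.covered_weight == 5

    def test_matches_independent_union_oracle(self, rng):
        for _ in range(30):
            sets, weights = random_instance(rng)
            cov = make_cov(sets)
            patients = toy_patients(weights)
            k = int(rng.integers(0, len(sets) + 1))
            chosen = [f"D{j}" for j in rng.choice(len(sets), size=k, replace=False)]
            res = evaluate_coverage(chosen, cov, patients)
            union = set().union(*(sets[int(c[1:])] for c in chosen)) if chosen else set()
            assert res.covered_weight == sum(weights[i] for i in union)

    def test_unknown_id_raises(self):
        cov = make_cov([{0}])
        with pytest.raises(KeyError):
            evaluate_coverage(["D7"], cov, toy_patients([1]))
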