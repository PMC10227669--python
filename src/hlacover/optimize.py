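"""Stage 2: choose a minimal-count or minimal-cost donor subset reaching a
target coverage.

The problem is weighted partial set cover: patient genotypes are elements
with occurrence weights p_i, each donor (or donor variant) j contributes a
coverage set S_j at cost c_j, and we minimize sum c_j x_j subject to the
covered weight reaching P = ceil(target_fraction * total weight).  Four
solution routes are provided:

* :func:`greedy_select` — lazy (heap-accelerated) greedy, optionally with a
  priority multiplier for 4/4 HLA-A/-B matches;
* :func:`greedy_cost_select` — the knockout-vs-full cost rule for scenario 3;
* :func:`solve_lp` — the LP relaxation (x_j, y_i in [0,1]); a lower bound on
  any integer solution's cost, never rounded into a selection;
* :func:`solve_ilp` — the exact ILP via HiGHS branch-and-bound;
* :func:`random_baseline` — donors drawn uniformly until the target is met,
  averaged over (by default) five trials.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .matching import CoverageSets
from .model import GenotypePool
from .scenarios import Scenario2Config

__all__ = [
    "SelectionResult",
    "LPResult",
    "RandomBaselineResult",
    "InfeasibleError",
    "greedy_select",
    "greedy_cost_select",
    "solve_lp",
    "solve_ilp",
    "random_baseline",
    "evaluate_coverage",
    "target_weight",
]


class InfeasibleError(RuntimeError):
    """The requested coverage exceeds what the union of all sets can reach."""

    def __init__(self, required: float, achievable: float, total: float):
        self.required = required
        self.achievable = achievable
        self.total = total
        super().__init__(
            f"required covered weight {required:g} exceeds the maximum achievable "
            f"{achievable:g} (of {total:g} total)"
        )


@dataclass
class SelectionResult:
    """A donor selection with its achieved coverage and objective."""

    selected: tuple[str, ...]
    covered_weight: int
    coverage_fraction: float
    objective: float
    feasible: bool = True
    optimal: bool | None = None
    tallies: dict = field(default_factory=dict)
    iterations: list[dict] = field(default_factory=list)


@dataclass
class LPResult:
    """Fractional optimum of the LP relaxation — a cost lower bound only."""

    fractional_x: dict[str, float]
    fractional_y: dict[int, float]
    objective: float


@dataclass
class RandomBaselineResult:
    trials: int
    donors_needed: list[int]
    costs: list[float]
    coverage_per_trial: list[float]
    mean: float
    sd: float
    mean_cost: float
    sd_cost: float
    feasible: bool


def target_weight(patients: GenotypePool, target_fraction: float) -> int:
    """P = ceil(target_fraction * total patient weight)."""
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    return math.ceil(target_fraction * patients.total_weight)


def _weights_array(patients: GenotypePool) -> np.ndarray:
    return np.asarray(patients.weights, dtype=float)


def _achievable(cov: CoverageSets, weights: np.ndarray) -> float:
    union: set[int] = set()
    for s in cov.sets.values():
        union |= s
    return float(weights[sorted(union)].sum()) if union else 0.0


def evaluate_coverage(
    selected: Iterable[str], cov: CoverageSets, patients: GenotypePool
) -> SelectionResult:
    """Recompute coverage of a selection from scratch (union semantics:
    overlapping S_j count each patient once) and tally metadata."""
    selected = tuple(selected)
    for key in selected:
        if key not in cov.sets:
            raise KeyError(f"unknown donor/variant id {key!r}")
    covered = cov.covered_union(selected)
    weights = _weights_array(patients)
    covered_weight = int(weights[sorted(covered)].sum()) if covered else 0
    total = patients.total_weight
    objective = float(sum(cov.costs[k] for k in selected))
    tallies: dict = {"n_knockouts": sum(1 for k in selected if cov.is_knockout[k])}
    tallies["n_full"] = len(selected) - tallies["n_knockouts"]
    if cov.match_counts is not None:
        # per covered patient, the best A/B match count over selected donors
        best: dict[int, int] = {}
        for k in selected:
            for i, mc in cov.match_counts[k].items():
                if i in covered and mc > best.get(i, 0):
                    best[i] = mc
        w4 = sum(int(weights[i]) for i, mc in best.items() if mc == 4)
        w3 = sum(int(weights[i]) for i, mc in best.items() if mc == 3)
        tallies["weight_4_matches"] = w4
        tallies["weight_3_matches"] = w3
    return SelectionResult(
        selected=selected,
        covered_weight=covered_weight,
        coverage_fraction=covered_weight / total,
        objective=objective,
        tallies=tallies,
    )


def _finalize(
    selected: Sequence[str],
    cov: CoverageSets,
    patients: GenotypePool,
    feasible: bool,
    iterations: list[dict] | None = None,
    optimal: bool | None = None,
) -> SelectionResult:
    res = evaluate_coverage(selected, cov, patients)
    res.feasible = feasible
    res.optimal = optimal
    if iterations is not None:
        res.iterations = iterations
    return res


def greedy_select(
    cov: CoverageSets,
    patients: GenotypePool,
    target_fraction: float,
    priority: Scenario2Config | None = None,
) -> SelectionResult:
    """Weighted greedy: repeatedly add the donor with the largest uncovered
    patient weight until the target is reached.

    With ``priority`` (scenario 2), the per-iteration gain is
    sum p_i * Prior(i) over uncovered patients in S_j, Prior(i) = prior4 when
    the donor-patient A/B match count is 4, else 1; the stopping rule still
    uses the plain covered weight.  Lazy evaluation is valid because the gain
    of a fixed donor can only shrink as coverage grows.  Ties break toward
    the lowest donor index.
    """
    weights = _weights_array(patients)
    P = target_weight(patients, target_fraction)
    if priority is not None and cov.match_counts is None:
        raise ValueError("priority selection needs coverage with A/B match counts")

    def gain(key: str, covered: set[int]) -> float:
        s = cov.sets[key] - covered
        if not s:
            return 0.0
        if priority is None or priority.prior4 == 1.0:
            return float(sum(weights[i] for i in s))
        mc = cov.match_counts[key]
        return float(
            sum(weights[i] * (priority.prior4 if mc.get(i) == 4 else 1.0) for i in s)
        )

    covered: set[int] = set()
    covered_weight = 0.0
    selected: list[str] = []
    iterations: list[dict] = []
    order = {key: pos for pos, key in enumerate(cov.ids)}
    heap = [(-gain(key, covered), order[key], key) for key in cov.ids]
    heapq.heapify(heap)
    while covered_weight < P and heap:
        neg_g, pos, key = heapq.heappop(heap)
        g_now = gain(key, covered)
        if heap and -heap[0][0] > g_now + 1e-12:
            heapq.heappush(heap, (-g_now, pos, key))
            continue
        if g_now <= 0.0:
            break
        newly = cov.sets[key] - covered
        added_weight = float(sum(weights[i] for i in newly))
        covered |= newly
        covered_weight += added_weight
        selected.append(key)
        iterations.append(
            {
                "id": key,
                "gain": g_now,
                "added_weight": added_weight,
                "cumulative_weight": covered_weight,
                "cumulative_fraction": covered_weight / patients.total_weight,
            }
        )
    return _finalize(selected, cov, patients, covered_weight >= P, iterations)


def greedy_cost_select(
    cov: CoverageSets,
    patients: GenotypePool,
    target_fraction: float,
    cost_ko: float | None = None,
) -> SelectionResult:
    """Cost-aware greedy for scenario 3 (full products vs knockouts).

    Per iteration: the best knockout variant covers uncovered weight S_K; a
    mini-greedy over full variants finds the smallest N_G whose union covers
    at least S_K uncovered weight (reaching S_F >= S_K).  The knockout is
    chosen iff its cost per covered patient (cost_ko + 1) / S_K is strictly
    smaller than N_G / S_F; otherwise the N_G full donors are committed.
    Both ratios are logged per iteration.
    """
    weights = _weights_array(patients)
    P = target_weight(patients, target_fraction)
    order = {key: pos for pos, key in enumerate(cov.ids)}
    if cost_ko is None:
        ko_costs = [cov.costs[k] for k in cov.ids if cov.is_knockout[k]]
        cost_ko = (max(ko_costs) - 1.0) if ko_costs else 10.0

    covered: set[int] = set()
    covered_weight = 0.0
    selected: list[str] = []
    chosen: set[str] = set()
    iterations: list[dict] = []

    def gain(key: str, extra: set[int]) -> float:
        s = cov.sets[key] - covered
        if extra:
            s = s - extra
        return float(sum(weights[i] for i in s))

    # lazy heaps are valid: a variant's uncovered weight only shrinks as
    # coverage grows, so stored (stale) gains are upper bounds
    ko_heap = [
        (-gain(k, set()), order[k], k) for k in cov.ids if cov.is_knockout[k]
    ]
    full_heap = [
        (-gain(k, set()), order[k], k) for k in cov.ids if not cov.is_knockout[k]
    ]
    heapq.heapify(ko_heap)
    heapq.heapify(full_heap)

    def pop_best(heap: list, extra: set[int]) -> tuple[str | None, float]:
        while heap:
            neg_g, pos, key = heapq.heappop(heap)
            if key in chosen:
                continue
            g_now = gain(key, extra)
            if heap and -heap[0][0] > g_now + 1e-12:
                heapq.heappush(heap, (-g_now, pos, key))
                continue
            if g_now <= 0.0:
                heapq.heappush(heap, (-g_now, pos, key))
                return None, 0.0
            return key, g_now
        return None, 0.0

    while covered_weight < P:
        best_ko, s_k = pop_best(ko_heap, set())
        # mini-greedy over full variants until >= s_k uncovered weight
        mini: list[tuple[str, float]] = []
        mini_covered: set[int] = set()
        s_f = 0.0
        while s_f < s_k or not mini:
            best_full, w = pop_best(full_heap, mini_covered)
            if best_full is None:
                break
            mini.append((best_full, w))
            mini_covered |= cov.sets[best_full] - covered
            s_f += w
        n_g = len(mini)
        if best_ko is None and n_g == 0:
            break  # nothing can cover anything further: best effort
        ko_ratio = (cost_ko + 1.0) / s_k if s_k > 0 else math.inf
        full_ratio = n_g / s_f if s_f > 0 else math.inf
        take_knockout = s_k > 0 and ko_ratio < full_ratio
        iterations.append(
            {
                "S_K": s_k,
                "N_G": n_g,
                "S_F": s_f,
                "knockout_cost_per_patient": ko_ratio,
                "full_cost_per_patient": full_ratio,
                "chose_knockout": bool(take_knockout),
            }
        )
        if take_knockout:
            picks = [best_ko]
            # the popped full variants were not committed; re-seed them with
            # their (still upper-bounding) last known gains
            for k, w in mini:
                heapq.heappush(full_heap, (-w, order[k], k))
        else:
            picks = [k for k, _ in mini]
            if best_ko is not None:
                heapq.heappush(ko_heap, (-s_k, order[best_ko], best_ko))
        for k in picks:
            newly = cov.sets[k] - covered
            covered |= newly
            covered_weight += float(sum(weights[i] for i in newly))
            chosen.add(k)
            selected.append(k)
            if covered_weight >= P:
                break
    return _finalize(selected, cov, patients, covered_weight >= P, iterations)


def _constraint_matrices(cov: CoverageSets, patients: GenotypePool, P: float):
    """Sparse constraints shared by LP and ILP.

    Variables are [x_1..x_m, y_1..y_n].  Rows: y_i - sum_{j: i in S_j} x_j <= 0
    for every patient, and -sum p_i y_i <= -P.
    """
    m = len(cov.ids)
    n = len(patients)
    weights = _weights_array(patients)
    rows, cols, vals = [], [], []
    for j, key in enumerate(cov.ids):
        for i in cov.sets[key]:
            rows.append(i)
            cols.append(j)
            vals.append(-1.0)
    for i in range(n):
        rows.append(i)
        cols.append(m + i)
        vals.append(1.0)
    for i in range(n):
        rows.append(n)
        cols.append(m + i)
        vals.append(-weights[i])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n + 1, m + n))
    b_ub = np.zeros(n + 1)
    b_ub[n] = -float(P)
    return A, b_ub


def _costs_vector(cov: CoverageSets, costs) -> np.ndarray:
    if costs is None:
        return np.array([cov.costs[k] for k in cov.ids], dtype=float)
    return np.asarray([costs[k] for k in cov.ids], dtype=float)


def solve_lp(
    cov: CoverageSets,
    patients: GenotypePool,
    target_fraction: float,
    costs=None,
) -> LPResult:
    """LP relaxation: minimize sum c_j x_j with x, y in [0,1] and covered
    weight >= P.  The fractional objective bounds any integer selection's
    cost from below; it is reported, never rounded into a selection."""
    weights = _weights_array(patients)
    P = target_weight(patients, target_fraction)
    ach = _achievable(cov, weights)
    if ach < P:
        raise InfeasibleError(P, ach, patients.total_weight)
    m, n = len(cov.ids), len(patients)
    c = np.concatenate([_costs_vector(cov, costs), np.zeros(n)])
    A, b_ub = _constraint_matrices(cov, patients, P)
    res = linprog(c, A_ub=A, b_ub=b_ub, bounds=(0.0, 1.0), method="highs")
    if not res.success:  # pragma: no cover - guarded by the achievability check
        raise RuntimeError(f"LP solver failed: {res.message}")
    x = res.x[:m]
    y = res.x[m:]
    return LPResult(
        fractional_x={k: float(x[j]) for j, k in enumerate(cov.ids) if x[j] > 1e-9},
        fractional_y={i: float(y[i]) for i in range(n) if y[i] > 1e-9},
        objective=float(res.fun),
    )


def solve_ilp(
    cov: CoverageSets,
    patients: GenotypePool,
    target_fraction: float,
    costs=None,
    time_limit: float = 300.0,
) -> SelectionResult:
    """Exact ILP (HiGHS branch-and-bound): binary x_j, minimize total cost.

    Coverage indicators y_i are kept continuous in [0,1]; with integer x the
    optimum is unchanged and the search tree stays smaller.  On time-limit
    expiry the best incumbent is returned flagged non-optimal.
    """
    weights = _weights_array(patients)
    P = target_weight(patients, target_fraction)
    ach = _achievable(cov, weights)
    if ach < P:
        raise InfeasibleError(P, ach, patients.total_weight)
    m, n = len(cov.ids), len(patients)
    c = np.concatenate([_costs_vector(cov, costs), np.zeros(n)])
    A, b_ub = _constraint_matrices(cov, patients, P)
    constraints = LinearConstraint(A, -np.inf, b_ub)
    integrality = np.concatenate([np.ones(m), np.zeros(n)])
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(0.0, 1.0),
        options={"time_limit": time_limit, "mip_rel_gap": 0.0},
    )
    timed_out = res.status == 1
    if res.x is None:
        if timed_out:
            raise RuntimeError("ILP hit the time limit before finding any incumbent")
        raise RuntimeError(f"ILP solver failed: {res.message}")
    selected = [k for j, k in enumerate(cov.ids) if res.x[j] > 0.5]
    return _finalize(selected, cov, patients, feasible=True, optimal=not timed_out)


def random_baseline(
    cov: CoverageSets,
    patients: GenotypePool,
    target_fraction: float,
    trials: int = 5,
    seed: int = 0,
    full_only: bool = False,
) -> RandomBaselineResult:
    """Donors drawn uniformly without replacement until the target is met.

    ``full_only`` restricts the draw to non-knockout products (the
    "random - full" baseline for scenario 3).  Reports per-trial counts and
    costs with their mean and (sample) standard deviation.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    weights = _weights_array(patients)
    P = target_weight(patients, target_fraction)
    pool = [k for k in cov.ids if not (full_only and cov.is_knockout[k])]
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    costs: list[float] = []
    fractions: list[float] = []
    all_met = True
    for _ in range(trials):
        order = rng.permutation(len(pool))
        covered: set[int] = set()
        covered_weight = 0.0
        cost = 0.0
        n_used = 0
        for idx in order:
            key = pool[idx]
            newly = cov.sets[key] - covered
            covered |= newly
            covered_weight += float(sum(weights[i] for i in newly))
            cost += cov.costs[key]
            n_used += 1
            if covered_weight >= P:
                break
        if covered_weight < P:
            all_met = False
        counts.append(n_used)
        costs.append(cost)
        fractions.append(covered_weight / patients.total_weight)
    ddof = 1 if trials > 1 else 0
    return RandomBaselineResult(
        trials=trials,
        donors_needed=counts,
        costs=costs,
        coverage_per_trial=fractions,
        mean=float(np.mean(counts)),
        sd=float(np.std(counts, ddof=ddof)),
        mean_cost=float(np.mean(costs)),
        sd_cost=float(np.std(costs, ddof=ddof)),
        feasible=all_met,
    )
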