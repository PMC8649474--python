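"""Optimal allocation under a fixed budget with per-treatment costs.

Under a budget constraint the design is xi = (p1, p2, p3, N): the total
sample size is no longer free but determined by the budget B, the cost per
subject in each of the eight treatment cells (A..H) and the expected cell
occupancies.  Expected counts follow the trial flow:

    E(N_A) = p1 N                     E(N_B) = (1 - p1) N
    E(N_C) = gamma1 p1 N              E(N_F) = gamma2 (1 - p1) N
    E(N_D) = (1 - gamma1) p1 p2 N     E(N_G) = (1 - gamma2) (1 - p1) p3 N
    E(N_E) = (1 - gamma1) p1 (1-p2) N E(N_H) = (1 - gamma2) (1 - p1) (1-p3) N

so the expected cost is linear in N and the affordable sample size is
N = B / c(xi) with c the expected per-subject cost.  Since the compound
criterion scales as 1/N, minimizing Phi at the affordable N is equivalent
to minimizing h(xi) * c(xi), which is solved by a domain search: an
exhaustive coarse grid over the proportions followed by local refinement
to a per-coordinate precision of 2e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .layout import (
    AllocationDesign,
    BALANCED,
    ObjectiveWeights,
    ResponseRates,
    Treatment,
    TrialScale,
)
from .variance import (
    CriterionValue,
    compound_criterion,
    second_stage_load_a,
    second_stage_load_b,
)

#: Refinement tolerance on each optimal proportion.
PROPORTION_TOL = 2e-5


class BudgetSpecError(ValueError):
    """Inconsistent or incomplete budget-mode specification."""


@dataclass(frozen=True)
class CostSchedule:
    """Per-subject cost of each treatment cell, in currency units.

    Each value is the cost of administering that cell's treatment for one
    stage to one subject.
    """

    costs: dict[Treatment, float]

    def __post_init__(self) -> None:
        missing = [t for t in Treatment if t not in self.costs]
        if missing:
            raise ValueError(f"cost schedule missing treatments {missing}")
        if any(c < 0 for c in self.costs.values()):
            raise ValueError("costs must be nonnegative")
        if not any(c > 0 for c in self.costs.values()):
            raise ValueError("at least one cost must be positive")

    def __getitem__(self, t: Treatment) -> float:
        return self.costs[t]

    @classmethod
    def from_values(cls, **kwargs: float) -> "CostSchedule":
        return cls({Treatment[k.upper()]: float(v) for k, v in kwargs.items()})

    @classmethod
    def weight_loss_example(cls, c_nut: float, c_phy: float) -> "CostSchedule":
        """Cost layout of the two-treatment weight-loss SMART.

        First-stage A = physical activity (PHY), B = nutrition (NUT).
        Responders continue their first-stage treatment (C = PHY, F = NUT);
        non-responders either switch to the other single treatment
        (D = NUT, G = PHY) or receive the combination, whose cost is the
        sum of the two single-treatment costs (E = H = NUT + PHY).  Both
        stages have equal length, so per-stage costs coincide.
        """
        return cls(
            {
                Treatment.A: c_phy,
                Treatment.B: c_nut,
                Treatment.C: c_phy,
                Treatment.D: c_nut,
                Treatment.E: c_nut + c_phy,
                Treatment.F: c_nut,
                Treatment.G: c_phy,
                Treatment.H: c_nut + c_phy,
            }
        )


def expected_cell_counts(
    design: AllocationDesign, rates: ResponseRates, n: float
) -> dict[Treatment, float]:
    """Expected number of subjects passing through each treatment cell.

    Non-responder cells carry the (1 - gamma) share of their branch; the
    counts conserve: A + B = N, C + D + E = p1 N, F + G + H = (1 - p1) N.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p1, p2, p3 = design.as_tuple()
    g1, g2 = rates.gamma1, rates.gamma2
    return {
        Treatment.A: p1 * n,
        Treatment.B: (1 - p1) * n,
        Treatment.C: g1 * p1 * n,
        Treatment.D: (1 - g1) * p1 * p2 * n,
        Treatment.E: (1 - g1) * p1 * (1 - p2) * n,
        Treatment.F: g2 * (1 - p1) * n,
        Treatment.G: (1 - g2) * (1 - p1) * p3 * n,
        Treatment.H: (1 - g2) * (1 - p1) * (1 - p3) * n,
    }


def per_subject_cost(
    design: AllocationDesign, rates: ResponseRates, costs: CostSchedule
) -> float:
    """Expected total cost per enrolled subject (N cancels)."""
    counts = expected_cell_counts(design, rates, n=1.0)
    return sum(costs[t] * counts[t] for t in Treatment)


def affordable_n(
    design: AllocationDesign,
    rates: ResponseRates,
    costs: CostSchedule,
    budget: float,
) -> tuple[float, int]:
    """Sample size the budget buys at a design: (continuous, reported floor)."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    c = per_subject_cost(design, rates, costs)
    if c <= 0:
        raise ValueError("unbounded sample size: per-subject cost is zero")
    n_cont = budget / c
    return n_cont, math.floor(n_cont)


@dataclass(frozen=True)
class BudgetOptimum:
    """Compound-optimal design under a fixed budget."""

    design: AllocationDesign
    n_continuous: float
    n_reported: int
    criterion: CriterionValue  # at sigma^2 = 1 and the continuous N
    re_balanced: float
    converged: bool = True


def _cost_vectors(
    grid: np.ndarray, rates: ResponseRates, costs: CostSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Expected second-stage cost of the A- and B-branches along the grid."""
    g1, g2 = rates.gamma1, rates.gamma2
    a2 = g1 * costs[Treatment.C] + (1 - g1) * (
        grid * costs[Treatment.D] + (1 - grid) * costs[Treatment.E]
    )
    b2 = g2 * costs[Treatment.F] + (1 - g2) * (
        grid * costs[Treatment.G] + (1 - grid) * costs[Treatment.H]
    )
    return a2, b2


def budget_objective(
    design: AllocationDesign,
    rates: ResponseRates,
    weights: ObjectiveWeights,
    costs: CostSchedule,
) -> float:
    """h(xi) * c(xi): proportional to Phi at the affordable sample size."""
    p1, p2, p3 = design.as_tuple()
    h = (
        second_stage_load_a(p2, rates.gamma1, weights) / p1
        + second_stage_load_b(p3, rates.gamma2, weights) / (1 - p1)
    )
    return h * per_subject_cost(design, rates, costs)


def optimal_design_budget(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    costs: CostSchedule,
    budget: float,
    grid_step: float = 0.01,
    sigma2: float = 1.0,
) -> BudgetOptimum:
    """Domain search for the compound-optimal design under a fixed budget.

    Two phases: an exhaustive coarse grid over the interior of the
    proportion cube (ties broken toward the lexicographically smallest
    point), then bound-constrained local refinement of h * c to a
    per-coordinate precision of 2e-5.  The reported sample size is the
    floor of the affordable continuous N; the criterion and the balanced
    design's relative efficiency use the continuous N on both sides.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    grid = np.arange(grid_step, 1.0, grid_step)
    fa = np.array([second_stage_load_a(float(x), rates.gamma1, weights) for x in grid])
    fb = np.array([second_stage_load_b(float(x), rates.gamma2, weights) for x in grid])
    a2, b2 = _cost_vectors(grid, rates, costs)
    p1 = grid[:, None, None]
    h = fa[None, :, None] / p1 + fb[None, None, :] / (1.0 - p1)
    c = (
        p1 * costs[Treatment.A]
        + (1.0 - p1) * costs[Treatment.B]
        + p1 * a2[None, :, None]
        + (1.0 - p1) * b2[None, None, :]
    )
    g = h * c
    i1, i2, i3 = np.unravel_index(np.argmin(g), g.shape)  # first = lexicographic
    x0 = np.array([grid[i1], grid[i2], grid[i3]])

    def objective(x: np.ndarray) -> float:
        return budget_objective(AllocationDesign(*x), rates, weights, costs)

    eps = 1e-9
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(eps, 1.0 - eps)] * 3,
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 1000},
    )
    converged = bool(res.success) and res.fun <= objective(x0) + 1e-12
    x = res.x if res.fun <= objective(x0) else x0
    design = AllocationDesign(*x)
    n_cont, n_rep = affordable_n(design, rates, costs, budget)
    crit = compound_criterion(design, rates, weights, TrialScale(sigma2, n_cont))
    # RE of the balanced design: each design carries its own affordable N
    phi_opt = budget_objective(design, rates, weights, costs)
    phi_bal = budget_objective(BALANCED, rates, weights, costs)
    return BudgetOptimum(
        design=design,
        n_continuous=n_cont,
        n_reported=n_rep,
        criterion=crit,
        re_balanced=phi_opt / phi_bal,
        converged=converged,
    )
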