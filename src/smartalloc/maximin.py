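"""Maximin robust optimal design over response-rate intervals.

The locally optimal design depends on the first-stage response rates
(gamma1, gamma2), which are rarely known at the design stage.  The maximin
approach protects against misspecification in three steps:

1. specify intervals for the two response rates and discretize them;
2. at every rate point of the grid, compute the locally optimal design and,
   for any candidate design, its relative efficiency
   RE = Phi(xi_LOD) / Phi(xi) at that rate point;
3. score each candidate by its smallest RE over the rate grid and pick the
   candidate with the largest such minimum — the maximin optimal design,
   whose score is the maximin value.

The procedure applies both under a fixed total sample size and under a
fixed budget; in budget mode every design (candidate and locally optimal
alike) is evaluated at its own affordable continuous sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .budget import (
    BudgetOptimum,
    CostSchedule,
    _cost_vectors,
    affordable_n,
    budget_objective,
    optimal_design_budget,
)
from .fixed_n import optimal_design_fixed_n
from .layout import AllocationDesign, ObjectiveWeights, ResponseRates, Treatment
from .variance import second_stage_load_a, second_stage_load_b


@dataclass(frozen=True)
class FixedNMode:
    """Evaluate designs under a fixed total sample size (N cancels in RE)."""


@dataclass(frozen=True)
class BudgetMode:
    """Evaluate designs under a fixed budget with the given cost schedule."""

    costs: CostSchedule
    budget: float


Mode = FixedNMode | BudgetMode


@dataclass(frozen=True)
class RateIntervals:
    """Closed intervals for the two response rates plus a discretization step."""

    gamma1_range: tuple[float, float]
    gamma2_range: tuple[float, float]
    rate_step: float = 0.01

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("gamma1_range", self.gamma1_range),
            ("gamma2_range", self.gamma2_range),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be a nonempty subinterval of [0,1]")
        if self.rate_step <= 0:
            raise ValueError("rate_step must be positive")

    @classmethod
    def around(
        cls,
        rates: ResponseRates,
        half_width: float = 0.05,
        rate_step: float = 0.01,
    ) -> "RateIntervals":
        """Symmetric intervals [gamma +/- half_width], clipped to [0, 1]."""
        return cls(
            (max(0.0, rates.gamma1 - half_width), min(1.0, rates.gamma1 + half_width)),
            (max(0.0, rates.gamma2 - half_width), min(1.0, rates.gamma2 + half_width)),
            rate_step,
        )

    def _axis(self, lo: float, hi: float) -> np.ndarray:
        if hi == lo:
            return np.array([lo])
        k = int(round((hi - lo) / self.rate_step))
        return np.linspace(lo, hi, k + 1)

    def grid(self) -> list[ResponseRates]:
        """All rate pairs of the discretized parameter space (row-major)."""
        g1 = self._axis(*self.gamma1_range)
        g2 = self._axis(*self.gamma2_range)
        return [ResponseRates(float(a), float(b)) for a in g1 for b in g2]


def _objective(
    design: AllocationDesign,
    rates: ResponseRates,
    weights: ObjectiveWeights,
    mode: Mode,
) -> float:
    """Criterion value up to mode-independent constants (sigma^2, B)."""
    if isinstance(mode, BudgetMode):
        return budget_objective(design, rates, weights, mode.costs)
    p1, p2, p3 = design.as_tuple()
    return (
        second_stage_load_a(p2, rates.gamma1, weights) / p1
        + second_stage_load_b(p3, rates.gamma2, weights) / (1 - p1)
    )


def _local_optimum(
    rates: ResponseRates, weights: ObjectiveWeights, mode: Mode
) -> AllocationDesign:
    if isinstance(mode, BudgetMode):
        return optimal_design_budget(weights, rates, mode.costs, mode.budget).design
    return optimal_design_fixed_n(weights, rates).design


def local_optima_over_grid(
    weights: ObjectiveWeights,
    intervals: RateIntervals,
    mode: Mode = FixedNMode(),
) -> dict[tuple[float, float], AllocationDesign]:
    """Locally optimal design at every rate point of the discretized intervals."""
    return {
        (r.gamma1, r.gamma2): _local_optimum(r, weights, mode)
        for r in intervals.grid()
    }


def min_relative_efficiency(
    candidate: AllocationDesign,
    weights: ObjectiveWeights,
    intervals: RateIntervals,
    mode: Mode = FixedNMode(),
) -> tuple[float, ResponseRates]:
    """Smallest RE of a candidate design over the rate grid, with its argmin."""
    best: tuple[float, ResponseRates] | None = None
    for rates in intervals.grid():
        lod = _local_optimum(rates, weights, mode)
        re = _objective(lod, rates, weights, mode) / _objective(
            candidate, rates, weights, mode
        )
        if best is None or re < best[0]:
            best = (re, rates)
    assert best is not None
    return best


@dataclass(frozen=True)
class MaximinResult:
    """Outcome of the maximin search."""

    design: AllocationDesign
    maximin_value: float
    worst_case_rates: ResponseRates
    n_reported: int | None = None  # budget mode only


def _objective_grid(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    grid: np.ndarray,
    mode: Mode,
) -> np.ndarray:
    """Vectorized mode objective over the design cube grid^3."""
    fa = np.array([second_stage_load_a(float(x), rates.gamma1, weights) for x in grid])
    fb = np.array([second_stage_load_b(float(x), rates.gamma2, weights) for x in grid])
    p1 = grid[:, None, None]
    h = fa[None, :, None] / p1 + fb[None, None, :] / (1.0 - p1)
    if isinstance(mode, BudgetMode):
        a2, b2 = _cost_vectors(grid, rates, mode.costs)
        c = (
            p1 * mode.costs[Treatment.A]
            + (1.0 - p1) * mode.costs[Treatment.B]
            + p1 * a2[None, :, None]
            + (1.0 - p1) * b2[None, None, :]
        )
        return h * c
    return h


def maximin_design(
    weights: ObjectiveWeights,
    intervals: RateIntervals,
    mode: Mode = FixedNMode(),
    design_grid_step: float = 0.01,
    refine: bool = True,
) -> MaximinResult:
    """Exhaustive maximin search over the design cube with local refinement.

    Candidates are the full interior design grid plus the locally optimal
    designs at every rate point (the maximin optimum need not be locally
    optimal for any single rate pair, but including the local optima makes
    the degenerate-interval case exact).  The incumbent is refined by a
    derivative-free search of the min-RE surface; the refinement is kept
    only if it improves the maximin value.
    """
    rate_points = intervals.grid()
    lods = [_local_optimum(r, weights, mode) for r in rate_points]
    lod_best = [
        _objective(d, r, weights, mode) for d, r in zip(lods, rate_points)
    ]

    grid = np.arange(design_grid_step, 1.0, design_grid_step)
    min_re_grid: np.ndarray | None = None
    argmin_idx: np.ndarray | None = None
    extras = np.array([d.as_tuple() for d in lods])  # explicit candidates
    min_re_extras = np.full(len(extras), np.inf)
    argmin_extras = np.zeros(len(extras), dtype=int)

    for k, rates in enumerate(rate_points):
        g = _objective_grid(weights, rates, grid, mode)
        re = lod_best[k] / g
        if min_re_grid is None:
            min_re_grid = re
            argmin_idx = np.full(re.shape, k, dtype=int)
        else:
            mask = re < min_re_grid
            min_re_grid[mask] = re[mask]
            argmin_idx[mask] = k
        for j, d in enumerate(lods):
            re_j = lod_best[k] / _objective(d, rates, weights, mode)
            if re_j < min_re_extras[j]:
                min_re_extras[j] = re_j
                argmin_extras[j] = k

    assert min_re_grid is not None and argmin_idx is not None
    i1, i2, i3 = np.unravel_index(np.argmax(min_re_grid), min_re_grid.shape)
    best_grid_val = float(min_re_grid[i1, i2, i3])
    best_x = np.array([grid[i1], grid[i2], grid[i3]])
    best_val = best_grid_val
    best_k = int(argmin_idx[i1, i2, i3])
    j = int(np.argmax(min_re_extras))
    if min_re_extras[j] >= best_val:
        best_val = float(min_re_extras[j])
        best_x = extras[j]
        best_k = int(argmin_extras[j])

    if refine:

        def neg_min_re(x: np.ndarray) -> float:
            if not np.all((x > 0.0) & (x < 1.0)):
                return np.inf
            d = AllocationDesign(*x)
            return -min(
                lod_best[k] / _objective(d, r, weights, mode)
                for k, r in enumerate(rate_points)
            )

        res = minimize(
            neg_min_re,
            best_x,
            method="Nelder-Mead",
            options={"xatol": 2e-5, "fatol": 1e-12, "maxiter": 2000},
        )
        if -res.fun > best_val:
            best_val = float(-res.fun)
            best_x = res.x
            best_k = int(
                np.argmin(
                    [
                        lod_best[k]
                        / _objective(AllocationDesign(*best_x), r, weights, mode)
                        for k, r in enumerate(rate_points)
                    ]
                )
            )

    # RE against a true local optimum cannot exceed 1; clip the tiny numerical
    # overshoot that a refined candidate can show against a refined optimum.
    best_val = min(best_val, 1.0)
    design = AllocationDesign(*best_x)
    n_rep = None
    if isinstance(mode, BudgetMode):
        n_rep = affordable_n(design, rate_points[best_k], mode.costs, mode.budget)[1]
    return MaximinResult(
        design=design,
        maximin_value=best_val,
        worst_case_rates=rate_points[best_k],
        n_reported=n_rep,
    )
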