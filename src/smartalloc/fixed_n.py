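"""Locally optimal allocation under a fixed total sample size.

With the total sample size N fixed, the compound-optimal design has a
closed form.  Writing the scale-free criterion as

    h(p1, p2, p3) = f_A(p2) / p1 + f_B(p3) / (1 - p1),

each coordinate solves a classical two-term Neyman-allocation problem, so
every optimal proportion is a ratio of square roots:

    p2* = sqrt(l13 + l14) / (sqrt(l13 + l14) + sqrt(l23 + l24))
    p3* = sqrt(l13 + l23) / (sqrt(l13 + l23) + sqrt(l14 + l24))
    p1* = sqrt(phi) / (sqrt(psi) + sqrt(phi))

where psi and phi are dimensionless aggregates combining the weights, the
response rates and the optimal second-stage proportions (they are
proportional to f_B(p3*) and f_A(p2*) respectively).  The second-stage
optima depend only on the weights; p1* additionally depends on the two
response rates but never on N.

A brute-force numerical oracle (:func:`oracle_fixed_n`) minimizes the
criterion directly on a grid with local refinement; it exists to verify the
closed forms and is independent of them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .layout import (
    AllocationDesign,
    BALANCED,
    ObjectiveWeights,
    ResponseRates,
    TrialScale,
)
from .variance import (
    CriterionValue,
    compound_criterion,
    compound_criterion_unit,
    relative_efficiency,
    second_stage_load_a,
    second_stage_load_b,
)


def _neyman_share(a: float, b: float, what: str) -> float:
    """sqrt(a) / (sqrt(a) + sqrt(b)), with boundary handling.

    When one of the two weight blocks vanishes the optimum sits on the
    boundary (all non-responders to one arm); a warning is emitted because
    boundary designs make the complementary contrasts inestimable.
    """
    if a < 0 or b < 0:
        raise ValueError("weight blocks must be nonnegative")
    if a == 0.0 and b == 0.0:
        raise ValueError(f"undefined proportion: both weight blocks for {what} are zero")
    if a == 0.0 or b == 0.0:
        warnings.warn(
            f"{what}: a weight block is zero; optimum is the boundary value "
            f"{1.0 if b == 0.0 else 0.0}",
            stacklevel=3,
        )
        return 1.0 if b == 0.0 else 0.0
    sa, sb = math.sqrt(a), math.sqrt(b)
    return sa / (sa + sb)


def optimal_second_stage(weights: ObjectiveWeights) -> tuple[float, float]:
    """Closed-form optimal second-stage proportions (p2*, p3*).

    Square-root (Neyman-type) allocation between the two non-responder arms
    of each branch; depends only on the objective weights, not on the
    response rates or the sample size.
    """
    l13, l14, l23, l24 = weights.as_tuple()
    p2 = _neyman_share(l13 + l14, l23 + l24, "p2*")
    p3 = _neyman_share(l13 + l23, l14 + l24, "p3*")
    return p2, p3


def aggregate_psi_phi(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    p2_star: float,
    p3_star: float,
) -> tuple[float, float]:
    """The (psi, phi) aggregates entering the first-stage optimum.

    psi collects the B-branch load, phi the A-branch load; both carry the
    common factor p2*(1-p2*) p3*(1-p3*), which cancels in the ratio that
    defines p1*.
    """
    l13, l14, l23, l24 = weights.as_tuple()
    g1, g2 = rates.gamma1, rates.gamma2
    common = p2_star * (1.0 - p2_star) * p3_star * (1.0 - p3_star)
    psi = (
        (g2 * p3_star + (1.0 - g2)) * (l13 + l23) * (1.0 - p3_star)
        + (g2 * (1.0 - p3_star) + (1.0 - g2)) * (l14 + l24) * p3_star
    ) * p2_star * (1.0 - p2_star)
    phi = (
        (g1 * p2_star + (1.0 - g1)) * (l13 + l14) * (1.0 - p2_star)
        + (g1 * (1.0 - p2_star) + (1.0 - g1)) * (l23 + l24) * p2_star
    ) * p3_star * (1.0 - p3_star)
    # psi = common * f_B(p3*), phi = common * f_A(p2*) for interior p2*, p3*
    del common
    return psi, phi


def optimal_first_stage(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    p2_star: float,
    p3_star: float,
) -> float:
    """Closed-form optimal first-stage proportion p1* = sqrt(phi)/(sqrt(psi)+sqrt(phi)).

    For boundary second-stage proportions the psi/phi aggregates degenerate
    to 0/0; the equivalent branch-load ratio sqrt(f_A)/(sqrt(f_A)+sqrt(f_B))
    (zero-weight terms dropped) is used there, which is the limiting form.
    """
    if 0.0 < p2_star < 1.0 and 0.0 < p3_star < 1.0:
        psi, phi = aggregate_psi_phi(weights, rates, p2_star, p3_star)
        if psi == 0.0 and phi == 0.0:
            raise ValueError("undefined first-stage proportion: psi = phi = 0")
        return math.sqrt(phi) / (math.sqrt(psi) + math.sqrt(phi))
    fa = second_stage_load_a(p2_star, rates.gamma1, weights)
    fb = second_stage_load_b(p3_star, rates.gamma2, weights)
    return math.sqrt(fa) / (math.sqrt(fa) + math.sqrt(fb))


@dataclass(frozen=True)
class FixedNOptimum:
    """Closed-form compound-optimal design under a fixed sample size."""

    design: AllocationDesign
    criterion: CriterionValue  # evaluated at sigma^2 = 1, N = 1
    psi: float
    phi_aggregate: float
    re_balanced: float


def optimal_design_fixed_n(
    weights: ObjectiveWeights, rates: ResponseRates
) -> FixedNOptimum:
    """Compose the closed-form optima into the full design (p1*, p2*, p3*).

    The reported criterion is evaluated at sigma^2 = 1, N = 1; rescale by
    sigma^2 / N for any other trial scale.
    """
    p2, p3 = optimal_second_stage(weights)
    p1 = optimal_first_stage(weights, rates, p2, p3)
    design = AllocationDesign(p1, p2, p3)
    if 0.0 < p2 < 1.0 and 0.0 < p3 < 1.0:
        psi, phi_agg = aggregate_psi_phi(weights, rates, p2, p3)
    else:
        psi = phi_agg = float("nan")
    crit = compound_criterion(design, rates, weights, TrialScale(1.0, 1.0))
    re_bal = relative_efficiency(BALANCED, design, rates, weights)
    return FixedNOptimum(
        design=design,
        criterion=crit,
        psi=psi,
        phi_aggregate=phi_agg,
        re_balanced=re_bal,
    )


# ---------------------------------------------------------------------------
# Numerical oracle
# ---------------------------------------------------------------------------


def criterion_grid(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    grid: np.ndarray,
) -> np.ndarray:
    """Vectorized h over the cube grid x grid x grid of (p1, p2, p3).

    Returns an array of shape (len(grid),) * 3 indexed [i1, i2, i3].
    """
    fa = np.array([second_stage_load_a(float(x), rates.gamma1, weights) for x in grid])
    fb = np.array([second_stage_load_b(float(x), rates.gamma2, weights) for x in grid])
    p1 = grid[:, None, None]
    return fa[None, :, None] / p1 + fb[None, None, :] / (1.0 - p1)


def oracle_fixed_n(
    weights: ObjectiveWeights,
    rates: ResponseRates,
    grid_step: float = 0.01,
    refine_tol: float = 1e-10,
) -> AllocationDesign:
    """Brute-force minimizer of the compound criterion (verification oracle).

    Exhaustive search on an interior grid with the given step, followed by
    bound-constrained local refinement from the best grid point.  Entirely
    independent of the closed forms; intended for tests.
    """
    if grid_step > 0.01:
        raise ValueError("oracle grid_step must be <= 0.01")
    grid = np.arange(grid_step, 1.0, grid_step)
    h = criterion_grid(weights, rates, grid)
    i1, i2, i3 = np.unravel_index(np.argmin(h), h.shape)
    x0 = np.array([grid[i1], grid[i2], grid[i3]])

    def objective(x: np.ndarray) -> float:
        # evaluate through the per-strategy variance formulas, not the
        # separable loads the closed form is derived from
        return compound_criterion_unit(AllocationDesign(*x), rates, weights)

    eps = 1e-9
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(eps, 1.0 - eps)] * 3,
        options={"ftol": refine_tol, "gtol": 1e-12, "maxiter": 500},
    )
    best = res.x if res.fun <= objective(x0) else x0
    return AllocationDesign(*best)
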