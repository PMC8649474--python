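"""Variances of IPW-weighted ATS means, contrast variances and the compound criterion.

The marginal mean of an embedded ATS is estimated by an inverse-probability
weighted (IPW) average of the outcomes of subjects whose trajectories are
consistent with the strategy.  Under a common outcome variance sigma^2 the
variance of this weighted mean has a closed form; for d1 it is

    Var(Ybar_d1) = sigma^2 * [gamma1 * p2 + (1 - gamma1)] / (N * p1 * p2)

and analogously for d2 (p2 -> 1-p2), d3 (gamma2, 1-p1, p3) and d4
(gamma2, 1-p1, 1-p3).  Weighted means of strategies starting with different
first-stage treatments are independent, so a contrast variance is the sum
of the two ATS variances.  The compound criterion is the weighted sum

    Phi = lambda13 Phi13 + lambda14 Phi14 + lambda23 Phi23 + lambda24 Phi24

over the four cross-first-stage contrasts; the design minimizing Phi is the
compound-optimal design.

Internally the N- and sigma^2-free form ``h = N * Phi / sigma^2`` is used
wherever possible: Phi scales exactly as sigma^2 / N, so h depends only on
the design, the response rates and the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

from .layout import (
    ALL_ATS,
    ATS,
    ATS_BY_ID,
    CONTRASTS,
    AllocationDesign,
    InfiniteCriterionError,
    ObjectiveWeights,
    ResponseRates,
    Treatment,
    TrialScale,
    require_valid,
)


class InfiniteVarianceError(ValueError):
    """An ATS variance is undefined because a required arm is empty."""


class UnsupportedContrastError(ValueError):
    """Contrast of two strategies sharing a first-stage treatment.

    The zero-covariance argument behind the contrast-variance formula only
    applies to strategies starting with different first-stage treatments;
    same-first-stage contrasts are rejected rather than guessed.
    """


def _ats_components(
    ats: ATS, design: AllocationDesign, rates: ResponseRates
) -> tuple[float, float, float]:
    """Return (gamma, q, P1) entering the strategy's variance formula.

    gamma is the response rate of the ATS's first-stage treatment, q the
    second-stage randomization probability of its non-responder arm, and P1
    the first-stage probability of its initial treatment.
    """
    if ats.first_stage is Treatment.A:
        gamma, p1 = rates.gamma1, design.p1
        q = design.p2 if ats.nonresponder_arm is Treatment.D else 1.0 - design.p2
    else:
        gamma, p1 = rates.gamma2, 1.0 - design.p1
        q = design.p3 if ats.nonresponder_arm is Treatment.G else 1.0 - design.p3
    return gamma, q, p1


def ats_variance_unit(
    design: AllocationDesign, rates: ResponseRates, ats: ATS | str
) -> float:
    """Variance of the weighted ATS mean at sigma^2 = 1, N = 1.

    Raises :class:`InfiniteVarianceError` when an arm the strategy needs is
    empty (and the limit is not finite).
    """
    if isinstance(ats, str):
        ats = ATS_BY_ID[ats]
    gamma, q, p1 = _ats_components(ats, design, rates)
    if p1 <= 0.0:
        raise InfiniteVarianceError(
            f"{ats.id}: first-stage arm {ats.first_stage} receives no subjects"
        )
    if q <= 0.0:
        if gamma == 1.0:
            # all subjects respond: no re-randomization, variance sigma^2/(N*P1)
            return 1.0 / p1
        raise InfiniteVarianceError(
            f"{ats.id}: non-responder arm {ats.nonresponder_arm} receives no subjects"
        )
    return (gamma * q + (1.0 - gamma)) / (p1 * q)


def ats_variance(
    design: AllocationDesign,
    rates: ResponseRates,
    scale: TrialScale,
    ats: ATS | str,
) -> float:
    """Variance of the IPW-weighted mean for one embedded strategy."""
    return scale.sigma2 / scale.n * ats_variance_unit(design, rates, ats)


def _check_cross_first_stage(pair: tuple[str, str]) -> tuple[ATS, ATS]:
    a, b = ATS_BY_ID[pair[0]], ATS_BY_ID[pair[1]]
    if a.first_stage is b.first_stage:
        raise UnsupportedContrastError(
            f"contrast {a.id}-{b.id} shares first-stage treatment "
            f"{a.first_stage}; only cross-first-stage contrasts are supported"
        )
    return a, b


def contrast_variance(
    design: AllocationDesign,
    rates: ResponseRates,
    scale: TrialScale,
    pair: tuple[str, str],
) -> float:
    """Variance of the difference of two cross-first-stage ATS means.

    The two weighted means are independent (different first-stage
    treatments), so the covariance term vanishes and the contrast variance
    is the plain sum of the two ATS variances.
    """
    a, b = _check_cross_first_stage(pair)
    return ats_variance(design, rates, scale, a) + ats_variance(design, rates, scale, b)


@dataclass(frozen=True)
class CriterionValue:
    """Compound criterion Phi and its per-contrast components."""

    phi: float
    per_contrast: dict[tuple[str, str], float]


def compound_criterion_unit(
    design: AllocationDesign,
    rates: ResponseRates,
    weights: ObjectiveWeights,
) -> float:
    """h(design) = N * Phi / sigma^2, the scale-free compound criterion.

    Zero-weight contrasts are dropped before any variance is evaluated, so
    boundary designs that zero out only unweighted contrasts evaluate
    finitely (the 0 * infinity ambiguity is resolved to 0).
    """
    require_valid(design, weights)
    total = 0.0
    unit = {}
    for pair, lam in zip(CONTRASTS, weights.as_tuple()):
        if lam <= 0.0:
            continue
        for ats_id in pair:
            if ats_id not in unit:
                unit[ats_id] = ats_variance_unit(design, rates, ats_id)
        total += lam * (unit[pair[0]] + unit[pair[1]])
    return total


def compound_criterion(
    design: AllocationDesign,
    rates: ResponseRates,
    weights: ObjectiveWeights,
    scale: TrialScale = TrialScale(),
) -> CriterionValue:
    """Evaluate the compound criterion Phi at a design.

    Returns both Phi and the map of per-contrast variances (zero-weight
    contrasts are reported only when they are finite at this design).
    """
    require_valid(design, weights)
    factor = scale.sigma2 / scale.n
    per: dict[tuple[str, str], float] = {}
    phi = 0.0
    for pair, lam in zip(CONTRASTS, weights.as_tuple()):
        if lam <= 0.0:
            try:
                per[pair] = factor * (
                    ats_variance_unit(design, rates, pair[0])
                    + ats_variance_unit(design, rates, pair[1])
                )
            except InfiniteVarianceError:
                pass
            continue
        per[pair] = factor * (
            ats_variance_unit(design, rates, pair[0])
            + ats_variance_unit(design, rates, pair[1])
        )
        phi += lam * per[pair]
    return CriterionValue(phi=phi, per_contrast=per)


def relative_efficiency(
    candidate: AllocationDesign,
    reference_optimal: AllocationDesign,
    rates: ResponseRates,
    weights: ObjectiveWeights,
    scale: TrialScale = TrialScale(),
) -> float:
    """RE = Phi(reference) / Phi(candidate), in (0, 1] when the reference is optimal.

    Independent of sigma^2 and, under a common fixed N, of N (both cancel in
    the ratio); an RE of 0.9 means the candidate needs 1/0.9 times as many
    subjects as the reference for the same precision.
    """
    num = compound_criterion(reference_optimal, rates, weights, scale).phi
    den = compound_criterion(candidate, rates, weights, scale).phi
    return num / den


# ---------------------------------------------------------------------------
# Second-stage "load" functions: h(design) separates as
#   h = f_A(p2) / p1 + f_B(p3) / (1 - p1)
# with f_A, f_B below.  These drive both the closed-form optimum and the
# vectorized grid searches.
# ---------------------------------------------------------------------------


def second_stage_load_a(
    p2: float, gamma1: float, weights: ObjectiveWeights
) -> float:
    """f_A(p2): contribution of the A-branch to p1 * h, zero-weight terms dropped."""
    wd, we = weights.lambda13 + weights.lambda14, weights.lambda23 + weights.lambda24
    total = 0.0
    if wd > 0.0:
        total += wd * (gamma1 * p2 + (1.0 - gamma1)) / p2
    if we > 0.0:
        total += we * (gamma1 * (1.0 - p2) + (1.0 - gamma1)) / (1.0 - p2)
    return total


def second_stage_load_b(
    p3: float, gamma2: float, weights: ObjectiveWeights
) -> float:
    """f_B(p3): contribution of the B-branch to (1 - p1) * h."""
    wg, wh = weights.lambda13 + weights.lambda23, weights.lambda14 + weights.lambda24
    total = 0.0
    if wg > 0.0:
        total += wg * (gamma2 * p3 + (1.0 - gamma2)) / p3
    if wh > 0.0:
        total += wh * (gamma2 * (1.0 - p3) + (1.0 - gamma2)) / (1.0 - p3)
    return total
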