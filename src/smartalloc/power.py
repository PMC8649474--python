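"""Statistical power for pairwise ATS comparisons at a chosen design.

For each cross-first-stage contrast the power of the z-test of
H0: mu_i = mu_i' is computed from the design-based contrast variance:

    1 - beta = NormCDF( |mu_i - mu_i'| / sqrt(Var(Ybar_i - Ybar_i')) - z_{1-alpha} )

with z_{1-alpha} replaced by z_{1-alpha/2} for a two-sided alternative.
The reference distribution is the standard normal (no t correction), and
the two-sided formula ignores the opposite-tail rejection region; both are
deliberate approximations, adequate for the moderate-to-large sample sizes
a SMART employs (for a zero effect the two-sided formula returns alpha/2,
not alpha).  No multiplicity adjustment is applied across the four
contrasts.

Under a fixed budget, the sample size entering the variances is first
computed from the budget, the costs and the design.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .budget import BudgetSpecError, CostSchedule, affordable_n
from .layout import (
    CONTRASTS,
    AllocationDesign,
    ObjectiveWeights,
    ResponseRates,
    TrialScale,
)
from .variance import contrast_variance


@dataclass(frozen=True)
class PowerSpec:
    """Effects to detect, type-I error rate and sidedness of the test."""

    effects: dict[tuple[str, str], float]  # contrast -> mu_i - mu_i'
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.effects) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts {sorted(unknown)}")


def power_one_sided(effect: float, var_diff: float, alpha: float) -> float:
    """Power of the one-sided z-test at the given contrast variance."""
    if var_diff <= 0:
        raise ValueError("contrast variance must be positive")
    return float(norm.cdf(abs(effect) / var_diff**0.5 - norm.ppf(1.0 - alpha)))


def power_two_sided(effect: float, var_diff: float, alpha: float) -> float:
    """Two-sided power via the alpha/2 substitution (opposite tail ignored)."""
    return power_one_sided(effect, var_diff, alpha / 2.0)


@dataclass(frozen=True)
class ContrastPower:
    contrast: tuple[str, str]
    variance: float
    effect: float
    standardized_effect: float
    power: float


@dataclass(frozen=True)
class PowerReport:
    """Per-contrast power at a design, plus the sample size actually used."""

    rows: tuple[ContrastPower, ...]
    n: float

    def power(self, pair: tuple[str, str]) -> float:
        return {r.contrast: r.power for r in self.rows}[pair]


def power_report(
    design: AllocationDesign,
    rates: ResponseRates,
    spec: PowerSpec,
    scale: TrialScale | None = None,
    costs: CostSchedule | None = None,
    budget: float | None = None,
    sigma2: float = 1.0,
) -> PowerReport:
    """Apply the power procedure to every contrast with a specified effect.

    Provide either ``scale`` (fixed sample size) or ``costs`` and ``budget``
    (the affordable sample size is computed first, using the continuous N).
    """
    if scale is None:
        if costs is None or budget is None:
            raise BudgetSpecError(
                "provide either scale or (costs and budget) to fix the sample size"
            )
        n_cont, _ = affordable_n(design, rates, costs, budget)
        scale = TrialScale(sigma2, n_cont)
    rows = []
    for pair in CONTRASTS:
        if pair not in spec.effects:
            continue
        var = contrast_variance(design, rates, scale, pair)
        effect = spec.effects[pair]
        p = (
            power_two_sided(effect, var, spec.alpha)
            if spec.two_sided
            else power_one_sided(effect, var, spec.alpha)
        )
        rows.append(
            ContrastPower(
                contrast=pair,
                variance=var,
                effect=effect,
                standardized_effect=abs(effect) / var**0.5,
                power=p,
            )
        )
    return PowerReport(rows=tuple(rows), n=scale.n)
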