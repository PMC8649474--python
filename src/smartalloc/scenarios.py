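"""Batch scenario runner: optimal-design tables over grids of inputs.

Builds the result tables a design report needs: one row per combination of
response rates, objective weights and (in budget mode) cost schedule, with
the optimal proportions, the affordable sample size where applicable, and
the relative efficiency of the balanced design.  Values are kept at full
precision; display rounding (2 decimals, half-up, as is conventional in
design tables) is applied only by the formatting helper.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Iterable, Sequence

import pandas as pd

from .budget import CostSchedule, optimal_design_budget
from .fixed_n import optimal_design_fixed_n
from .layout import ObjectiveWeights, ResponseRates, Treatment


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding, matching printed design tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def fixed_n_table(
    rate_sets: Sequence[ResponseRates],
    weight_sets: Sequence[ObjectiveWeights],
) -> pd.DataFrame:
    """Locally optimal designs under a fixed sample size, one row per cell."""
    rows: list[dict[str, Any]] = []
    for rates in rate_sets:
        for weights in weight_sets:
            opt = optimal_design_fixed_n(weights, rates)
            rows.append(
                {
                    "gamma1": rates.gamma1,
                    "gamma2": rates.gamma2,
                    "lambda13": weights.lambda13,
                    "lambda14": weights.lambda14,
                    "lambda23": weights.lambda23,
                    "lambda24": weights.lambda24,
                    "p1_star": opt.design.p1,
                    "p2_star": opt.design.p2,
                    "p3_star": opt.design.p3,
                    "re_balanced": opt.re_balanced,
                }
            )
    return pd.DataFrame(rows)


def budget_table(
    rate_sets: Sequence[ResponseRates],
    weight_sets: Sequence[ObjectiveWeights],
    cost_sets: Sequence[CostSchedule],
    budget: float,
) -> pd.DataFrame:
    """Locally optimal designs under a fixed budget, one row per cell."""
    rows: list[dict[str, Any]] = []
    for costs in cost_sets:
        for rates in rate_sets:
            for weights in weight_sets:
                opt = optimal_design_budget(weights, rates, costs, budget)
                rows.append(
                    {
                        "gamma1": rates.gamma1,
                        "gamma2": rates.gamma2,
                        "lambda13": weights.lambda13,
                        "lambda14": weights.lambda14,
                        "lambda23": weights.lambda23,
                        "lambda24": weights.lambda24,
                        "cost_A": costs[Treatment.A],
                        "cost_B": costs[Treatment.B],
                        "p1_star": opt.design.p1,
                        "p2_star": opt.design.p2,
                        "p3_star": opt.design.p3,
                        "n_star": opt.n_reported,
                        "re_balanced": opt.re_balanced,
                    }
                )
    return pd.DataFrame(rows)


def display_rounded(table: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Copy of a result table with proportions/RE rounded half-up for display."""
    out = table.copy()
    for col in ("p1_star", "p2_star", "p3_star", "re_balanced"):
        if col in out:
            out[col] = out[col].map(lambda v: round_half_up(v, digits))
    return out


def _parse_weights(raw: Iterable[float]) -> ObjectiveWeights:
    vals = list(raw)
    if len(vals) != 4:
        raise ValueError("weights need exactly four entries (l13, l14, l23, l24)")
    return ObjectiveWeights(*vals)


def run_scenarios(config: dict[str, Any]) -> pd.DataFrame:
    """Run a batch of scenarios from a parsed configuration mapping.

    Schema::

        mode: fixed_n | budget
        rates: [[gamma1, gamma2], ...]
        weights: [[l13, l14, l23, l24], ...]
        budget: <number>            # budget mode only
        costs:                      # budget mode only, one of:
          - {A: .., B: .., ..., H: ..}
          - {nut: .., phy: ..}      # two-treatment weight-loss layout

    Returns the full-precision result table (empty for empty scenario
    lists).
    """
    mode = config.get("mode", "fixed_n")
    rate_sets = [ResponseRates(*map(float, r)) for r in config.get("rates", [])]
    weight_sets = [_parse_weights(w) for w in config.get("weights", [])]
    if mode == "fixed_n":
        if not rate_sets or not weight_sets:
            return pd.DataFrame()
        return fixed_n_table(rate_sets, weight_sets)
    if mode != "budget":
        raise ValueError(f"unknown mode {mode!r}")
    if "budget" not in config:
        raise ValueError("budget mode requires a 'budget' entry")
    cost_sets = []
    for c in config.get("costs", []):
        keys = {str(k).lower() for k in c}
        if keys == {"nut", "phy"}:
            cost_sets.append(
                CostSchedule.weight_loss_example(float(c["nut"]), float(c["phy"]))
            )
        else:
            cost_sets.append(CostSchedule.from_values(**{k: float(v) for k, v in c.items()}))
    if not rate_sets or not weight_sets or not cost_sets:
        return pd.DataFrame()
    return budget_table(rate_sets, weight_sets, cost_sets, float(config["budget"]))
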