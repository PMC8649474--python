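# smartalloc

Optimal allocation of subjects to treatments in two-stage **sequential
multiple assignment randomized trials (SMARTs)**.

In the prototypical two-stage SMART, subjects are randomized to one of two
first-stage treatments (A with probability *p₁*, B with 1 − *p₁*).
Responders continue to a fixed second-stage treatment; non-responders are
re-randomized (after A: to D with probability *p₂*, else E; after B: to G
with probability *p₃*, else H). Four adaptive treatment strategies (ATSs)
d₁–d₄ are embedded in this design, and the common primary aim is the
pairwise comparison of strategies that start with different first-stage
treatments. Equal randomization (*p₁* = *p₂* = *p₃* = 0.5) is customary
but not optimal: this package computes how to split subjects so that those
comparisons are as precise as possible.

## The model

The marginal mean of strategy dᵢ is estimated by an inverse-probability
weighted (IPW) mean; under a common outcome variance σ² its design
variance is, for d₁,

    Var(Ȳ_d1) = σ² [γ₁ p₂ + (1 − γ₁)] / (N p₁ p₂)

with γ₁ the response rate to A (analogous forms for d₂–d₄). The four
cross-first-stage contrast variances Φᵢᵢ′ = Var(Ȳ_dᵢ) + Var(Ȳ_dᵢ′) are
combined into a compound criterion

    Φ = λ₁₃Φ₁₃ + λ₁₄Φ₁₄ + λ₂₃Φ₂₃ + λ₂₄Φ₂₄,   Σλ = 1,

whose minimizer is the compound-optimal design. Under a **fixed sample
size** the optimum is closed-form Neyman-type (square-root) allocation,
e.g. p₂\* = √(λ₁₃+λ₁₄) / (√(λ₁₃+λ₁₄) + √(λ₂₃+λ₂₄)). Under a **fixed
budget** with per-treatment costs, the affordable N = B / c(ξ) depends on
the design through the expected cell counts, and the optimum is found by a
domain search (coarse grid plus refinement to 2 × 10⁻⁵ per proportion).
**Maximin** designs maximize the worst-case relative efficiency over
response-rate intervals; a **power** module and a **Monte-Carlo
simulator** (which validates every formula empirically) round out the
toolkit.

## Worked example

Weight-loss SMART: first-stage physical activity (A) vs nutrition (B),
response rates (γ₁, γ₂) = (0.15, 0.25), 70% of the weight on comparing the
two single-second-stage-treatment strategies:

```python
from smartalloc import ObjectiveWeights, ResponseRates, optimal_design_fixed_n

opt = optimal_design_fixed_n(
    ObjectiveWeights(0.70, 0.10, 0.10, 0.10), ResponseRates(0.15, 0.25)
)
```

prints (see `examples/fixed_sample_size_design.py`):

```
optimal design: p1*=0.5061  p2*=0.6667  p3*=0.6667
criterion at sigma^2=1, N=1: Phi* = 6.5590
RE of the balanced design:   0.9110
```

Two-thirds of non-responders should go to the single second-stage
treatments, first-stage randomization stays near 1:1, and the balanced
design would need ~1/0.91 ≈ 10% more subjects for the same precision.
With a budget of 100,000, nutrition at 300/month and physical activity at
50/month, the budget-constrained optimum shifts subjects toward the
cheaper first-stage arm and affords 243 subjects
(`examples/fixed_budget_design.py`):

```
optimal design: p1*=0.5586  p2*=0.5173  p3*=0.5631
affordable sample size: N* = 243 (continuous 243.01)
RE of the balanced design: 0.9763
```

The other scripts in `examples/` cover the maximin robustness analysis and
the simulation-checked power calculation. The same functionality is
available from the shell:

```sh
smartalloc design-fixed-n --gamma1 0.15 --gamma2 0.25 --weights 0.7,0.1,0.1,0.1
smartalloc design-budget --gamma1 0.15 --gamma2 0.25 --weights 0.25,0.25,0.25,0.25 \
    --budget 100000 --cost-nut 300 --cost-phy 50
smartalloc maximin --gamma1 0.15 --gamma2 0.25 --weights 0.7,0.1,0.1,0.1
smartalloc reproduce-tables --config scenarios.yaml --csv
```

## Layout

- `src/smartalloc/layout.py` — trial topology, strategies, design parameters
- `src/smartalloc/variance.py` — IPW variances, contrasts, compound criterion
- `src/smartalloc/fixed_n.py` — closed-form optimum + numerical oracle
- `src/smartalloc/budget.py` — cost model, cell counts, budget domain search
- `src/smartalloc/maximin.py` — robust designs over response-rate intervals
- `src/smartalloc/power.py` — per-contrast power
- `src/smartalloc/simulate.py` — trial simulator and IPW estimator
- `src/smartalloc/scenarios.py`, `cli.py` — batch tables and the CLI
- `docs/methods.md` — modelling assumptions and numerical choices
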