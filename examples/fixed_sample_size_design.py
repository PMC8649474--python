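"""Locally optimal allocation for a two-stage SMART with a fixed sample size.

Scenario: the weight-loss SMART (first-stage physical activity vs
nutrition), response rates (0.15, 0.25), with 70% of the design weight on
comparing the two single-second-stage-treatment strategies.
"""

from smartalloc import ObjectiveWeights, ResponseRates, optimal_design_fixed_n

weights = ObjectiveWeights(0.70, 0.10, 0.10, 0.10)
rates = ResponseRates(gamma1=0.15, gamma2=0.25)

opt = optimal_design_fixed_n(weights, rates)

print(f"optimal design: p1*={opt.design.p1:.4f}  p2*={opt.design.p2:.4f}  p3*={opt.design.p3:.4f}")
print(f"criterion at sigma^2=1, N=1: Phi* = {opt.criterion.phi:.4f}")
print(f"RE of the balanced design:   {opt.re_balanced:.4f}")

# p2* = p3* = 2/3: two-thirds of the non-responders go to the single
# second-stage treatments that the heavily weighted contrast compares.
# p1* stays near 1/2, and equal randomization loses about 9% efficiency
# (the balanced design would need ~1/0.91 times as many subjects).
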