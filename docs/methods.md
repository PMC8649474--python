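# Methods

## Design model and assumptions

The package targets the prototypical two-stage SMART with two first-stage
treatments, deterministic continuation for responders and re-randomization
of non-responders, yielding four embedded adaptive treatment strategies
(d₁–d₄). The modelling assumptions are:

- **Common outcome variance.** Every subject's outcome has variance σ²
  regardless of strategy or responder status; only cell means may differ.
- **Independence across first-stage arms.** Outcomes of subjects starting
  on different first-stage treatments are independent, so the covariance
  between their weighted means vanishes and a contrast variance is the sum
  of two strategy variances. Contrasts of strategies sharing a first-stage
  treatment (d₁ vs d₂, d₃ vs d₄) are *rejected* rather than computed: the
  zero-covariance argument does not apply to them, they would require a
  covariance model, and the design methodology never evaluates them.
- **Known response rates (or intervals).** The locally optimal design
  treats (γ₁, γ₂) as known; the maximin machinery replaces point guesses
  by intervals.

The strategy variance used throughout is the large-sample design variance
obtained by plugging the *expected* weight sums into the variance of the
IPW ratio estimator. For a finite trial the realized-denominator estimator
deviates from this formula at order 1/N (about 3% at N = 100, 0.3% at
N = 1000); the simulator exposes this, see below.

## Parameters

| parameter | meaning | default / constraint |
|---|---|---|
| p₁, p₂, p₃ | randomization probabilities (stage 1; A-non-responders to D; B-non-responders to G) | in [0, 1]; boundary values legal but rejected when they starve a positively weighted contrast |
| γ₁, γ₂ | response rates to the first-stage treatments | in [0, 1] |
| λ₁₃, λ₁₄, λ₂₃, λ₂₄ | weights of the four cross-first-stage contrasts | nonnegative, normalized to sum 1 on construction |
| σ², N | outcome variance and total sample size | σ² > 0; N > 0, continuous internally, reported N integral |
| c_A … c_H | per-subject cost of each treatment cell | ≥ 0, at least one positive |
| B | total budget | > 0 |

Weight ordering follows the running-text convention (λ₁₃, λ₁₄, λ₂₃, λ₂₄).
Published summary tables sometimes order the middle pair the other way
round; for the weight sets used in the worked example (three of the four
entries equal) the two orderings coincide.

## Optimizers and numerical choices

**Fixed sample size.** The criterion separates as
h = f_A(p₂)/p₁ + f_B(p₃)/(1 − p₁), so each coordinate is a two-term
Neyman-allocation problem and every optimal proportion is a square-root
ratio. When a whole weight block is zero the optimum is the boundary value
(returned with a warning, since the complementary contrasts become
inestimable). A brute-force oracle (interior grid, step ≤ 0.01, then
L-BFGS-B refinement of the Table-style criterion) verifies the closed
forms; closed form and oracle agree to ~10⁻⁶ per coordinate over random
weight/rate draws.

**Fixed budget.** N is eliminated analytically: the affordable sample
size is N = B/c(ξ) with c the expected per-subject cost from the expected
cell counts, and since Φ ∝ 1/N the search minimizes h(ξ)·c(ξ) over the
proportions only. The search is a coarse interior grid (default step
0.01; grid ties broken toward the lexicographically smallest point)
followed by L-BFGS-B refinement; the refinement tolerance targets 2 × 10⁻⁵
per proportion. Reported N\* is the floor of the continuous affordable N
(never exceeding the budget); the criterion and relative efficiencies use
the continuous N on both sides of the ratio.

**Maximin.** Rate intervals default to ±0.05 around the nominal guesses,
discretized at step 0.01; the candidate space is the full interior design
grid (default step 0.01) *plus* the locally optimal designs at every rate
point, with Nelder-Mead refinement of the incumbent's min-RE surface
(kept only when it improves). Including the local optima makes the
degenerate-interval case exact (maximin value 1 by construction), and the
final value is clipped at 1 to absorb refinement round-off of order 10⁻⁹.
The candidate grid is searched exhaustively rather than restricted to
local optima because the maximin optimum need not be locally optimal for
any single rate pair.

**Power.** Standard-normal reference (no t correction) and, for two-sided
tests, the α/2 substitution that ignores the opposite-tail rejection
region — at a zero effect the two-sided formula returns α/2, not α. Both
are deliberate approximations adequate for the sample sizes SMARTs use; no
multiplicity adjustment is applied across the four contrasts. Sample-size
inversion (solving N for a target power) is left to the caller.

## Simulator

The simulator draws first-stage arm ~ Bernoulli(p₁), response ~
Bernoulli(γ of the arm), deterministic continuation for responders,
second-stage arm ~ Bernoulli(p₂ or p₃) for non-responders, and a Normal
outcome per terminal cell. Normality is a choice (the design theory only
uses means and variances); it makes the power cross-validation exact up to
Monte-Carlo error. One integer seed governs the whole replicate stream;
replicates are generated in memory-bounded chunks from a single generator.

Two estimators are reported per strategy: the ratio estimator ΣWY/ΣW
(realized weight-sum denominator) and ΣWY/N (expected denominator). The
ratio estimator is exactly unbiased when cell means are homogeneous within
a strategy and carries an O(1/N) bias otherwise; the expected-denominator
version is exactly unbiased in general. The variance formulas are
validated against the ratio estimator under homogeneous cell means at
N = 1000 with 10⁵ replicates, where the O(1/N) remainder is far below the
Monte-Carlo resolution; at small N the same comparison would show the
~1/N deviation, which is a property of the large-sample formula, not an
implementation error.

What the synthetic trials do *not* emulate: dropout and missing tailoring
measurements, non-normal or heteroscedastic outcomes, clustering (shared
therapists, centres), and interim adaptation. Passing tests therefore
demonstrate the internal consistency of the design formulas under their
own assumptions, not robustness to those violations.

## Known limitations

- Only the prototypical two-stage topology: two first-stage arms, no
  re-randomization of responders, more stages/arms out of scope.
- Same-first-stage contrasts unsupported (no covariance model).
- Reported sample sizes floor the continuous value; published tables
  appear to round in a few cells, so off-by-one differences against such
  tables are possible away from the verified anchor values.
- The power formulas are normal approximations and are anti-conservative
  for very small N.

## Problem sizes used in the validation suite

The test suite verifies the closed forms against the oracle on 200 random
draws, Monte-Carlo-validates variances on six interior scenarios
(N = 1000, 10⁵ replicates each, 3 MC-standard-error bands), validates
power at formula power ≈ 0.75 (N = 400, 2 × 10⁴ trials), and runs the
maximin-vs-local comparison on the nine worked-example scenarios with the
full 0.01 design grid. These sizes were chosen so that statistical checks
sit in the regime the formulas describe while the whole suite stays fast.
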