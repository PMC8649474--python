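"""Monte-Carlo SMART trial simulator and IPW estimator.

The simulator draws subject-level trajectories through the prototypical
two-stage SMART — first-stage arm, response, second-stage arm — and a
normal outcome with a mean set per terminal treatment cell.  It serves as
the independent oracle for the variance formulas and the power procedure:
the empirical variance of the IPW-weighted mean across replicate trials is
compared against the closed-form design variances, and the empirical
rejection rate of the z-test against the normal-approximation power.

The IPW estimator of an ATS marginal mean is

    Ybar_di = sum_j W_j Y_j / sum_j W_j

over subjects consistent with the strategy, where W_j is the reciprocal of
the probability of the trajectory actually received (responders on A:
1/p1; A-non-responders to D: 1/(p1 p2); and so on).  The denominator is
the realized weight sum, whose expectation is N for every ATS.

The common-variance formulas assume outcomes share one variance sigma^2
within each ATS; the simulator also supports heterogeneous cell means
(responder vs non-responder), under which the marginal ATS variance
exceeds the residual variance and the closed forms no longer apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import (
    ALL_ATS,
    ATS,
    ATS_BY_ID,
    AllocationDesign,
    ResponseRates,
    Treatment,
)

#: Column layout of a simulated trial table.
DATASET_COLUMNS = ("id", "stage1", "response", "stage2", "weight", "outcome")


@dataclass(frozen=True)
class OutcomeModel:
    """Normal outcome means per terminal cell (C..H) and a residual sd."""

    means: dict[Treatment, float]
    sd: float = 1.0

    def __post_init__(self) -> None:
        terminal = (
            Treatment.C,
            Treatment.D,
            Treatment.E,
            Treatment.F,
            Treatment.G,
            Treatment.H,
        )
        missing = [t for t in terminal if t not in self.means]
        if missing:
            raise ValueError(f"outcome model missing cells {missing}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def homogeneous(
        cls, mu_a: float, mu_b: float, sd: float = 1.0
    ) -> "OutcomeModel":
        """Equal means within each first-stage branch.

        Under this configuration every ATS starting with A has marginal
        mean ``mu_a`` (likewise B and ``mu_b``) and the total within-ATS
        outcome variance equals ``sd**2``, the regime the closed-form
        design variances assume.
        """
        return cls(
            {
                Treatment.C: mu_a,
                Treatment.D: mu_a,
                Treatment.E: mu_a,
                Treatment.F: mu_b,
                Treatment.G: mu_b,
                Treatment.H: mu_b,
            },
            sd=sd,
        )

    def marginal_mean(self, ats: ATS | str, rates: ResponseRates) -> float:
        """mu_i = gamma * mu(responder cell) + (1 - gamma) * mu(non-responder cell)."""
        if isinstance(ats, str):
            ats = ATS_BY_ID[ats]
        gamma = rates.gamma1 if ats.first_stage is Treatment.A else rates.gamma2
        return gamma * self.means[ats.responder_arm] + (1.0 - gamma) * self.means[
            ats.nonresponder_arm
        ]


def trajectory_weight(
    stage1: Treatment, response: bool, stage2: Treatment, design: AllocationDesign
) -> float:
    """IPW weight of one realized trajectory: 1 / P(trajectory | design)."""
    p1 = design.p1 if stage1 is Treatment.A else 1.0 - design.p1
    if p1 <= 0:
        raise ValueError(f"realized first-stage arm {stage1} has zero probability")
    if response:
        return 1.0 / p1
    if stage2 is Treatment.D:
        q = design.p2
    elif stage2 is Treatment.E:
        q = 1.0 - design.p2
    elif stage2 is Treatment.G:
        q = design.p3
    elif stage2 is Treatment.H:
        q = 1.0 - design.p3
    else:
        raise ValueError(f"{stage2} is not a non-responder arm")
    if q <= 0:
        raise ValueError(f"realized second-stage arm {stage2} has zero probability")
    return 1.0 / (p1 * q)


def generate_trial(
    design: AllocationDesign,
    rates: ResponseRates,
    model: OutcomeModel,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate one SMART of ``n`` subjects; identical seeds give identical tables.

    Returns a data frame with columns ``id, stage1, response, stage2,
    weight, outcome`` (one row per subject).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    to_a = rng.random(n) < design.p1
    gamma = np.where(to_a, rates.gamma1, rates.gamma2)
    respond = rng.random(n) < gamma
    u = rng.random(n)
    stage2 = np.empty(n, dtype="<U1")
    stage2[to_a & respond] = "C"
    stage2[~to_a & respond] = "F"
    a_nr = to_a & ~respond
    b_nr = ~to_a & ~respond
    stage2[a_nr] = np.where(u[a_nr] < design.p2, "D", "E")
    stage2[b_nr] = np.where(u[b_nr] < design.p3, "G", "H")
    means = np.array([model.means[Treatment(s)] for s in stage2])
    outcome = means + model.sd * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "stage1": np.where(to_a, "A", "B"),
            "response": respond.astype(int),
            "stage2": stage2,
            "outcome": outcome,
        }
    )
    df["weight"] = ipw_weights(df, design)
    return df[list(DATASET_COLUMNS)]


def ipw_weights(dataset: pd.DataFrame, design: AllocationDesign) -> np.ndarray:
    """Subject-level IPW weights recomputed from the trajectory columns."""
    p1 = np.where(dataset["stage1"].to_numpy() == "A", design.p1, 1.0 - design.p1)
    if np.any(p1 <= 0):
        raise ValueError("a realized first-stage arm has zero probability")
    q = np.ones(len(dataset))
    s2 = dataset["stage2"].to_numpy()
    nonresp = dataset["response"].to_numpy() == 0
    q = np.where(nonresp & (s2 == "D"), design.p2, q)
    q = np.where(nonresp & (s2 == "E"), 1.0 - design.p2, q)
    q = np.where(nonresp & (s2 == "G"), design.p3, q)
    q = np.where(nonresp & (s2 == "H"), 1.0 - design.p3, q)
    if np.any(q[nonresp] <= 0):
        raise ValueError("a realized second-stage arm has zero probability")
    return 1.0 / (p1 * q)


def consistency_mask(dataset: pd.DataFrame, ats: ATS | str) -> np.ndarray:
    """Subjects whose realized trajectory is consistent with the strategy."""
    if isinstance(ats, str):
        ats = ATS_BY_ID[ats]
    s1 = dataset["stage1"].to_numpy() == ats.first_stage.value
    resp = dataset["response"].to_numpy() == 1
    s2 = dataset["stage2"].to_numpy()
    return s1 & (
        (resp & (s2 == ats.responder_arm.value))
        | (~resp & (s2 == ats.nonresponder_arm.value))
    )


@dataclass(frozen=True)
class AtsEstimate:
    """IPW estimate of one ATS marginal mean from a single trial.

    ``mean`` divides by the realized weight sum (a ratio estimator, exactly
    unbiased when cell means are homogeneous within the ATS, otherwise
    biased at order 1/N); ``mean_expected_denominator`` divides by N, the
    expectation of the weight sum, and is exactly unbiased in general.
    Both are reported to expose the difference.
    """

    ats: str
    mean: float
    mean_expected_denominator: float
    weight_sum: float
    n_consistent: int


def ipw_marginal_mean(dataset: pd.DataFrame, ats: ATS | str) -> AtsEstimate:
    """Weighted ATS mean with the realized weight sum as denominator."""
    if isinstance(ats, str):
        ats = ATS_BY_ID[ats]
    mask = consistency_mask(dataset, ats)
    if not mask.any():
        raise ValueError(f"no subjects consistent with {ats.id}; estimate undefined")
    w = dataset["weight"].to_numpy()[mask]
    y = dataset["outcome"].to_numpy()[mask]
    return AtsEstimate(
        ats=ats.id,
        mean=float(np.sum(w * y) / np.sum(w)),
        mean_expected_denominator=float(np.sum(w * y) / len(dataset)),
        weight_sum=float(np.sum(w)),
        n_consistent=int(mask.sum()),
    )


def replicate_estimates(
    design: AllocationDesign,
    rates: ResponseRates,
    model: OutcomeModel,
    n: int,
    replicates: int,
    seed: int,
    chunk: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """IPW estimates for all four ATSs across replicate trials (vectorized).

    Returns, per ATS id, arrays ``mean``, ``mean_expected_denominator``
    and ``weight_sum`` of length ``replicates``.  Replicates are simulated in chunks to bound memory;
    the whole stream is governed by the single integer seed.
    """
    if chunk is None:
        # cap the working set at a few tens of MB regardless of n
        chunk = min(20_000, max(1_000, 2_000_000 // max(n, 1)))
    rng = np.random.default_rng(seed)
    out = {
        a.id: {"mean": [], "mean_expected_denominator": [], "weight_sum": []}
        for a in ALL_ATS
    }
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        to_a = rng.random((r, n)) < design.p1
        gamma = np.where(to_a, rates.gamma1, rates.gamma2)
        respond = rng.random((r, n)) < gamma
        u = rng.random((r, n))
        z = rng.standard_normal((r, n))
        for ats in ALL_ATS:
            first_a = ats.first_stage is Treatment.A
            s1 = to_a if first_a else ~to_a
            q = design.p2 if first_a else design.p3
            hi_arm = ats.nonresponder_arm in (Treatment.D, Treatment.G)
            nr_pick = (u < q) if hi_arm else (u >= q)
            cons_r = s1 & respond
            cons_nr = s1 & ~respond & nr_pick
            p1 = design.p1 if first_a else 1.0 - design.p1
            q_arm = q if hi_arm else 1.0 - q
            w = cons_r / p1 + cons_nr / (p1 * q_arm)
            mu_r = model.means[ats.responder_arm]
            mu_nr = model.means[ats.nonresponder_arm]
            y = (cons_r * mu_r + cons_nr * mu_nr) + (cons_r | cons_nr) * model.sd * z
            wsum = w.sum(axis=1)
            wy = (w * y).sum(axis=1)
            out[ats.id]["mean"].append(wy / wsum)
            out[ats.id]["mean_expected_denominator"].append(wy / n)
            out[ats.id]["weight_sum"].append(wsum)
        done += r
    return {
        k: {kk: np.concatenate(vv) for kk, vv in d.items()} for k, d in out.items()
    }


def empirical_power_one_sided(
    design: AllocationDesign,
    rates: ResponseRates,
    model: OutcomeModel,
    n: int,
    pair: tuple[str, str],
    alpha: float,
    replicates: int,
    seed: int,
) -> float:
    """Rejection rate of the one-sided z-test across simulated trials.

    The test statistic uses the design-based contrast variance (known
    sigma^2), mirroring the normal-approximation power formula it
    validates; the alternative's direction is taken from the sign of the
    true mean difference under the outcome model.
    """
    from scipy.stats import norm

    from .layout import TrialScale
    from .variance import contrast_variance

    est = replicate_estimates(design, rates, model, n, replicates, seed)
    diff = est[pair[0]]["mean"] - est[pair[1]]["mean"]
    true_diff = model.marginal_mean(pair[0], rates) - model.marginal_mean(
        pair[1], rates
    )
    if true_diff < 0:
        diff = -diff
    var = contrast_variance(
        design, rates, TrialScale(model.sd**2, n), pair
    )
    z = diff / var**0.5
    return float(np.mean(z > norm.ppf(1.0 - alpha)))


def empirical_variance(
    design: AllocationDesign,
    rates: ResponseRates,
    model: OutcomeModel,
    n: int,
    replicates: int,
    seed: int,
) -> dict[str, float]:
    """Sample variance of the IPW mean across replicate trials, per ATS."""
    est = replicate_estimates(design, rates, model, n, replicates, seed)
    return {k: float(np.var(v["mean"], ddof=1)) for k, v in est.items()}
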