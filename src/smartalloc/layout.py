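"""Topology of the prototypical two-stage SMART and its design parameters.

The prototypical SMART randomizes subjects to two first-stage treatments
(A with probability ``p1``, B with ``1 - p1``).  Responders continue to a
fixed second-stage treatment (C after A, F after B); non-responders are
re-randomized (D vs E after A with probability ``p2`` for D, G vs H after B
with probability ``p3`` for G).  Four adaptive treatment strategies (ATSs)
are embedded in this layout:

====  ===========  =========  =============
ATS   first stage  responder  non-responder
====  ===========  =========  =============
d1    A            C          D
d2    A            C          E
d3    B            F          G
d4    B            F          H
====  ===========  =========  =============

This module holds the domain types shared by every other module: the
allocation design (``p1``, ``p2``, ``p3``), the first-stage response rates
(``gamma1``, ``gamma2``), the objective weights of the compound criterion,
and the trial scale (outcome variance and total sample size).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Treatment(str, enum.Enum):
    """The eight treatment cells of the prototypical SMART."""

    A = "A"  # first-stage
    B = "B"  # first-stage
    C = "C"  # responders after A
    D = "D"  # non-responders after A, probability p2
    E = "E"  # non-responders after A, probability 1-p2
    F = "F"  # responders after B
    G = "G"  # non-responders after B, probability p3
    H = "H"  # non-responders after B, probability 1-p3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ATS:
    """An adaptive treatment strategy embedded in the prototypical SMART."""

    id: str
    first_stage: Treatment
    responder_arm: Treatment
    nonresponder_arm: Treatment


#: The four embedded strategies, in canonical order d1..d4.
ATS_D1 = ATS("d1", Treatment.A, Treatment.C, Treatment.D)
ATS_D2 = ATS("d2", Treatment.A, Treatment.C, Treatment.E)
ATS_D3 = ATS("d3", Treatment.B, Treatment.F, Treatment.G)
ATS_D4 = ATS("d4", Treatment.B, Treatment.F, Treatment.H)
ALL_ATS: tuple[ATS, ...] = (ATS_D1, ATS_D2, ATS_D3, ATS_D4)
ATS_BY_ID: dict[str, ATS] = {a.id: a for a in ALL_ATS}

#: The four cross-first-stage contrasts, keyed as in the compound criterion.
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("d1", "d3"),
    ("d1", "d4"),
    ("d2", "d3"),
    ("d2", "d4"),
)


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class AllocationDesign:
    """Randomization probabilities xi = (p1, p2, p3).

    ``p1`` is the probability of first-stage treatment A, ``p2`` the
    probability that an A-non-responder receives D, and ``p3`` the
    probability that a B-non-responder receives G.  Boundary values 0 and 1
    are legal data (single-objective optima sit on the boundary) but make
    some ATS variances undefined; :func:`validate_design` flags the
    contradictions.
    """

    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1", _check_prob("p1", self.p1))
        object.__setattr__(self, "p2", _check_prob("p2", self.p2))
        object.__setattr__(self, "p3", _check_prob("p3", self.p3))

    @property
    def is_interior(self) -> bool:
        return all(0.0 < p < 1.0 for p in (self.p1, self.p2, self.p3))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


#: Equal randomization at every decision point.
BALANCED = AllocationDesign(0.5, 0.5, 0.5)


@dataclass(frozen=True)
class ResponseRates:
    """First-stage response rates gamma1 (to A) and gamma2 (to B)."""

    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        _check_prob("gamma1", self.gamma1)
        _check_prob("gamma2", self.gamma2)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights (lambda13, lambda14, lambda23, lambda24) of the compound criterion.

    The weights are nonnegative and are normalized to sum to one on
    construction; ``was_normalized`` records whether rescaling happened.
    The ordering follows the running-text convention (13, 14, 23, 24).
    """

    lambda13: float
    lambda14: float
    lambda23: float
    lambda24: float
    was_normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        vals = (self.lambda13, self.lambda14, self.lambda23, self.lambda24)
        if any(v < 0 for v in vals):
            raise ValueError(f"weights must be nonnegative, got {vals}")
        total = sum(vals)
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            object.__setattr__(self, "lambda13", self.lambda13 / total)
            object.__setattr__(self, "lambda14", self.lambda14 / total)
            object.__setattr__(self, "lambda23", self.lambda23 / total)
            object.__setattr__(self, "lambda24", self.lambda24 / total)
            object.__setattr__(self, "was_normalized", True)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.lambda13, self.lambda14, self.lambda23, self.lambda24)

    def for_contrast(self, pair: tuple[str, str]) -> float:
        return dict(zip(CONTRASTS, self.as_tuple()))[pair]


@dataclass(frozen=True)
class TrialScale:
    """Common outcome variance sigma^2 and total sample size N.

    ``n`` may be non-integral internally (the budget-constrained search
    works with a continuous sample size); reported sample sizes are
    integers.
    """

    sigma2: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")


class InfiniteCriterionError(ValueError):
    """A positively weighted contrast touches an arm with zero allocation."""


def _arm_requirements(ats: ATS) -> dict[str, str]:
    """Map of design constraints an ATS needs to be estimable.

    Returns {requirement: arm description} where requirement is one of
    'p1>0', 'p1<1', 'p2>0', 'p2<1', 'p3>0', 'p3<1'.
    """
    if ats.first_stage is Treatment.A:
        reqs = {"p1>0": "first-stage arm A"}
        if ats.nonresponder_arm is Treatment.D:
            reqs["p2>0"] = "non-responder arm D"
        else:
            reqs["p2<1"] = "non-responder arm E"
    else:
        reqs = {"p1<1": "first-stage arm B"}
        if ats.nonresponder_arm is Treatment.G:
            reqs["p3>0"] = "non-responder arm G"
        else:
            reqs["p3<1"] = "non-responder arm H"
    return reqs


def _requirement_holds(req: str, design: AllocationDesign) -> bool:
    p = {"p1": design.p1, "p2": design.p2, "p3": design.p3}[req[:2]]
    return p > 0.0 if req.endswith(">0") else p < 1.0


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a design against a set of objective weights."""

    ok: bool
    problems: tuple[str, ...] = ()
    boundary: bool = False


def validate_design(
    design: AllocationDesign, weights: ObjectiveWeights
) -> ValidationReport:
    """Check that every positively weighted contrast is estimable.

    A contrast Phi_ii' with positive weight requires every arm that either
    of its two strategies passes through to receive a positive share of
    subjects; otherwise the corresponding variance, and hence the compound
    criterion, is infinite.
    """
    problems: list[str] = []
    for pair, lam in zip(CONTRASTS, weights.as_tuple()):
        if lam <= 0:
            continue
        for ats_id in pair:
            ats = ATS_BY_ID[ats_id]
            for req, arm in _arm_requirements(ats).items():
                if not _requirement_holds(req, design):
                    problems.append(
                        f"contrast {pair[0]}-{pair[1]} (weight {lam:g}) needs "
                        f"{arm} populated, but {req} fails for design "
                        f"{design.as_tuple()}"
                    )
    return ValidationReport(
        ok=not problems,
        problems=tuple(problems),
        boundary=not design.is_interior,
    )


def require_valid(design: AllocationDesign, weights: ObjectiveWeights) -> None:
    """Raise :class:`InfiniteCriterionError` if the design is inadmissible."""
    report = validate_design(design, weights)
    if not report.ok:
        raise InfiniteCriterionError(
            "infinite-criterion design: " + "; ".join(report.problems)
        )
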