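"""Treatment simulators: GLUT1 inhibition, glucose starvation, sucker's gambit.

Two treatments map onto the game's parameters.  A GLUT1 inhibitor blocks
transport through the channels a cell has already paid for, lowering the
per-transporter encounter rate ``a``.  Glucose starvation (e.g. dietary
restriction or 2-deoxy-D-glucose) lowers the available resource ``R``.
Either way the payoff curve drops pointwise, but the treated ESS also moves
closer to the team optimum: treatment reduces inter-cell competitiveness
and thereby partially "rescues the cells from themselves".

The sucker's gambit exploits that trade-off by sequencing: let cells evolve
the highly competitive transporter-rich ESS of the untreated (or resource
boosted) environment, then switch the environment.  If transporter
production is *plastic*, cells immediately re-equilibrate and the endpoint
is just the treated ESS.  If it is *genetic* (heritable, changing only
across generations), the inherited strategy is evaluated under the treated
parameters — a mismatched payoff that is negative for every neighborhood
size N >= 2 in both reference scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

from .equilibrium import EquilibriumResult, solve_ess
from .model import (
    BASELINE_PARAMS,
    ModelParams,
    ScalingAssumption,
    StrategyProfile,
    fitness,
)

__all__ = [
    "TherapyScenario",
    "GambitResult",
    "INHIBITOR_EFFICACY_A",
    "STARVATION_EFFICACY_R",
    "glut1_inhibitor_scenario",
    "glucose_starvation_scenario",
    "treated_ess",
    "mismatched_payoff",
    "gambit_sweep",
]

TherapyKind = Literal["glut1_inhibitor", "glucose_starvation"]
Efficacy = Literal["low", "medium", "high", "custom"]
Hypothesis = Literal["plastic", "genetic"]

#: Treated encounter rate per inhibitor efficacy tier (1/transporter).
INHIBITOR_EFFICACY_A: dict[str, float] = {
    "low": 1.0 / 800_000.0,
    "medium": 1.0 / 1_000_000.0,
    "high": 1.0 / 1_200_000.0,
}

#: Treated resource availability per starvation efficacy tier.
STARVATION_EFFICACY_R: dict[str, float] = {
    "low": 7000.0,
    "medium": 5000.0,
    "high": 3000.0,
}


@dataclass(frozen=True)
class TherapyScenario:
    """Baseline and treated parameter sets for one treatment.

    ``pre_boost``, if given, is the environment in which the resident
    strategy evolved before treatment (e.g. deliberately raised R to drive
    competitiveness up first); by default residents come from ``baseline``.
    """

    baseline: ModelParams
    treated: ModelParams
    therapy_kind: TherapyKind
    efficacy: Efficacy = "custom"
    hypothesis: Hypothesis = "genetic"
    pre_boost: ModelParams | None = None

    def __post_init__(self) -> None:
        b, t = self.baseline, self.treated
        if self.therapy_kind == "glut1_inhibitor":
            if not (t.R == b.R and t.k == b.k):
                raise ValueError("a GLUT1 inhibitor scenario may only change a")
            if t.a > b.a:
                raise ValueError("inhibitor must not increase the encounter rate a")
        elif self.therapy_kind == "glucose_starvation":
            if not (t.a == b.a and t.k == b.k):
                raise ValueError("a glucose starvation scenario may only change R")
            if t.R > b.R:
                raise ValueError("starvation must not increase resource availability R")
        else:
            raise ValueError(f"unknown therapy_kind {self.therapy_kind!r}")

    @property
    def resident_env(self) -> ModelParams:
        """Environment whose ESS the residents carry into treatment."""
        return self.pre_boost if self.pre_boost is not None else self.baseline


@dataclass(frozen=True)
class GambitResult:
    """Outcome of the sucker's gambit at one neighborhood size.

    ``v_resident`` is the pre-treatment ESS the cells inherited; ``payoff``
    its per-cell payoff under the treated parameters; ``reference_ess`` the
    ESS the cells would reach if they re-equilibrated (the plastic endpoint).
    """

    N: int
    v_resident: float
    payoff: float
    reference_ess: EquilibriumResult


def glut1_inhibitor_scenario(
    baseline: ModelParams = BASELINE_PARAMS,
    efficacy: Efficacy = "medium",
    a: float | None = None,
    hypothesis: Hypothesis = "genetic",
    pre_boost: ModelParams | None = None,
) -> TherapyScenario:
    """Build an inhibitor scenario from an efficacy tier or a custom treated a."""
    if a is None:
        try:
            a = INHIBITOR_EFFICACY_A[efficacy]
        except KeyError:
            raise ValueError(
                f"efficacy {efficacy!r} requires an explicit treated encounter rate a"
            ) from None
    else:
        efficacy = "custom"
    return TherapyScenario(
        baseline=baseline,
        treated=replace(baseline, a=a),
        therapy_kind="glut1_inhibitor",
        efficacy=efficacy,
        hypothesis=hypothesis,
        pre_boost=pre_boost,
    )


def glucose_starvation_scenario(
    baseline: ModelParams = BASELINE_PARAMS,
    efficacy: Efficacy = "medium",
    R: float | None = None,
    hypothesis: Hypothesis = "genetic",
    pre_boost: ModelParams | None = None,
) -> TherapyScenario:
    """Build a starvation scenario from an efficacy tier or a custom treated R."""
    if R is None:
        try:
            R = STARVATION_EFFICACY_R[efficacy]
        except KeyError:
            raise ValueError(
                f"efficacy {efficacy!r} requires an explicit treated resource level R"
            ) from None
    else:
        efficacy = "custom"
    return TherapyScenario(
        baseline=baseline,
        treated=replace(baseline, R=R),
        therapy_kind="glucose_starvation",
        efficacy=efficacy,
        hypothesis=hypothesis,
        pre_boost=pre_boost,
    )


def treated_ess(
    scenario: TherapyScenario,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> EquilibriumResult:
    """ESS under the treated parameters (the plastic-hypothesis endpoint)."""
    return solve_ess(scenario.treated, N, scaling)


def mismatched_payoff(
    v_resident: float,
    treated: ModelParams,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Per-cell payoff of an inherited symmetric strategy in the treated game.

    Evaluates G at v = u = v_resident with the treated parameters; under
    depletion-zone scaling this is R_t*(1 - exp(-a_t*v)) - k*v and may well
    be negative — the cells keep paying for transporters the new
    environment no longer rewards.
    """
    if v_resident <= 0:
        raise ValueError(f"v_resident must be > 0; got {v_resident}")
    profile = StrategyProfile(v=v_resident, u=v_resident, N=int(N))
    return fitness(profile, treated, scaling)


def gambit_sweep(
    scenario: TherapyScenario,
    N_values: Iterable[int],
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> list[GambitResult]:
    """Sucker's-gambit outcomes across neighborhood sizes.

    For each N the residents play the ESS of the pre-treatment environment;
    their payoff is evaluated under the treated parameters (genetic
    hypothesis).  Under the plastic hypothesis the endpoint is instead the
    ``reference_ess`` carried in each result.
    """
    scaling = ScalingAssumption.coerce(scaling)
    results: list[GambitResult] = []
    for N in N_values:
        N = int(N)
        resident = solve_ess(scenario.resident_env, N, scaling)
        results.append(
            GambitResult(
                N=N,
                v_resident=resident.v_star,
                payoff=mismatched_payoff(resident.v_star, scenario.treated, N, scaling),
                reference_ess=treated_ess(scenario, N, scaling),
            )
        )
    return results
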