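"""ESS and team-optimum solvers for the transporter game.

The evolutionarily stable strategy (ESS) is the symmetric transporter count
``v*`` at which no cell can gain by unilateral deviation: the fitness
gradient vanishes at ``v = u = v*`` and the curvature is negative.  The team
optimum instead maximizes the group payoff ``N*G`` with respect to the total
transporter count, and satisfies ``k = R*a*exp(-a*v)`` — identical to the
N = 1 ESS, where the average-benefit term of the gradient vanishes and only
the marginal benefit remains.

For N >= 2 the ESS weighs the *average* return per transporter alongside the
marginal return; since the gain function is concave the average exceeds the
marginal, so cells overinvest relative to the team optimum and everyone's
payoff drops: a tragedy of the commons.

Root finding works on the dimensionless variable ``w = a_eff * v`` (the ESS
condition depends on the parameters only through the cost ratio k/(R*a) and
N), with a bracketed Brent solve — scale-free and unconditionally convergent
on a sign change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from scipy.optimize import brentq

from .model import (
    ModelParams,
    ScalingAssumption,
    StrategyProfile,
    effective_params,
    fitness,
    fitness_curvature,
)

__all__ = [
    "EquilibriumResult",
    "NoPositiveEquilibriumError",
    "ess_condition_residual",
    "solve_ess",
    "solve_team_optimum",
    "competitiveness",
    "sweep_N",
]

# Brent solve on w = a_eff*v: default bracket and tolerance.  w = 50 puts the
# exponential terms at ~2e-22; the bracket grows adaptively if the condition
# has not changed sign by then (possible for very small cost ratios).
_W_LO = 1e-12
_W_HI = 50.0
_W_XTOL = 1e-12
_W_HI_MAX = 1e8


class NoPositiveEquilibriumError(ValueError):
    """Raised when k >= R*a, so no positive transporter equilibrium exists."""


class ConvergenceError(RuntimeError):
    """Raised when the bracketed root find cannot isolate the equilibrium."""


@dataclass(frozen=True)
class EquilibriumResult:
    """A solved transporter equilibrium and its diagnostics.

    ``v_star`` is transporters per cell, ``v_star_total = N * v_star`` per
    depletion zone.  ``payoff`` is the per-cell payoff at the symmetric
    profile.  ``residual`` is the absolute defect of the solved first-order
    condition (cost units); ``curvature`` is d2G/dv2 at the ESS (None for a
    team optimum, which is verified through d2(NG)/dx2 < 0 analytically).
    """

    kind: Literal["ess", "team_optimum"]
    v_star: float
    v_star_total: float
    payoff: float
    residual: float
    curvature: float | None
    N: int
    scaling: ScalingAssumption
    converged: bool = True


def _sym_profile(v: float, N: int) -> StrategyProfile:
    return StrategyProfile(v=v, u=v, N=N)


def _scaled_condition(w: float, kappa: float, N: int, scaling: ScalingAssumption) -> float:
    """ESS first-order condition in dimensionless form, RHS(w)/(R*a) - kappa.

    ``w = a_eff * v`` and ``kappa = k / (R_eff * a_eff)``.  Under
    depletion-zone scaling the symmetric-point gradient gives

        f(w) = exp(-w)/N + ((N-1)/N) * (1 - exp(-w))/w - kappa,

    the first term the marginal return on the neighborhood harvest, the
    second the average return captured by raising one's share.  Under
    crowding (R, a constant, x = N*v so a*x = N*w) the same differentiation
    gives

        f(w) = exp(-N*w)/N + (N-1) * (1 - exp(-N*w)) / (N**2 * w) - kappa.
    """
    if scaling is ScalingAssumption.DEPLETION_ZONE:
        em1 = -math.expm1(-w)  # 1 - e^{-w}
        return math.exp(-w) / N + (N - 1) / N * em1 / w - kappa
    em1 = -math.expm1(-N * w)
    return math.exp(-N * w) / N + (N - 1) * em1 / (N * N * w) - kappa


def ess_condition_residual(
    v: float,
    params: ModelParams,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Defect of the symmetric ESS condition at per-cell strategy ``v``.

    Returns RHS(v) - k in cost units, where RHS is the symmetric-point
    fitness gradient's benefit side; zero exactly at the ESS.  As v -> 0+
    the residual tends to R*a - k (the net marginal value of the first
    transporter), which is why k < R*a is needed for a positive root.
    """
    scaling = ScalingAssumption.coerce(scaling)
    if v <= 0:
        raise ValueError(f"ess_condition_residual requires v > 0; got {v}")
    N = int(N)
    # Under depletion-zone scaling a_eff*x = (a/N)*(N*v) = a*v, so the natural
    # dimensionless variable is w = a*v with the ORIGINAL a under both rules;
    # likewise R_eff*a_eff == R*a under both, so kappa = k/(R*a) throughout.
    w = params.a * v
    return _scaled_condition(w, params.cost_ratio, N, scaling) * params.R * params.a


def _solve_condition(kappa: float, N: int, scaling: ScalingAssumption) -> float:
    """Root w* of the dimensionless ESS condition, with adaptive upper bracket."""
    f = lambda w: _scaled_condition(w, kappa, N, scaling)
    lo, hi = _W_LO, _W_HI
    flo = f(lo)
    if flo <= 0:  # pragma: no cover - guarded by the kappa < 1 check upstream
        raise ConvergenceError(
            f"ESS condition non-positive at lower bracket w={lo} (kappa={kappa}, N={N})"
        )
    while f(hi) > 0:
        hi *= 10.0
        if hi > _W_HI_MAX:
            raise ConvergenceError(
                f"no sign change of the ESS condition for w in [{lo}, {_W_HI_MAX}] "
                f"(kappa={kappa}, N={N}, scaling={scaling.value})"
            )
    return brentq(f, lo, hi, xtol=_W_XTOL)


def _require_existence(params: ModelParams) -> None:
    # R_eff * a_eff == R * a under both scalings, so one check covers all N.
    if params.k >= params.R * params.a:
        raise NoPositiveEquilibriumError(
            f"k = {params.k} >= R*a = {params.R * params.a}: the first transporter "
            "already costs more than it returns, so no positive equilibrium exists"
        )


def solve_ess(
    params: ModelParams,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> EquilibriumResult:
    """Solve for the ESS transporter count per cell in an N-cell neighborhood.

    For N = 1 this reduces to the closed form v* = ln(R*a/k)/a.  The solved
    point is returned with its payoff at the symmetric profile, the
    first-order residual, and the (negative) curvature certifying a fitness
    peak.
    """
    scaling = ScalingAssumption.coerce(scaling)
    N = int(N)
    _require_existence(params)
    w_star = _solve_condition(params.cost_ratio, N, scaling)
    v_star = w_star / params.a
    profile = _sym_profile(v_star, N)
    return EquilibriumResult(
        kind="ess",
        v_star=v_star,
        v_star_total=N * v_star,
        payoff=fitness(profile, params, scaling),
        residual=abs(ess_condition_residual(v_star, params, N, scaling)),
        curvature=fitness_curvature(profile, params, scaling),
        N=N,
        scaling=scaling,
    )


def solve_team_optimum(
    params: ModelParams,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> EquilibriumResult:
    """Solve for the symmetric strategy maximizing the group payoff N*G.

    Setting d(NG)/dx = R_eff*a_eff*exp(-a_eff*x) - k to zero fixes the TOTAL
    transporter count x_team = ln(R*a/k)/a_eff.  Under depletion-zone scaling
    (a_eff = a/N) the per-cell optimum ln(R*a/k)/a is independent of N; under
    crowding the fixed total is split evenly, v_team = x_team/N.  Concavity
    is automatic: d2(NG)/dx2 = -R_eff*a_eff^2*exp(-a_eff*x) < 0.
    """
    scaling = ScalingAssumption.coerce(scaling)
    N = int(N)
    _require_existence(params)
    eff = effective_params(params, N, scaling)
    x_team = math.log(eff.R * eff.a / params.k) / eff.a
    v_team = x_team / N
    profile = _sym_profile(v_team, N)
    residual = abs(eff.R * eff.a * math.exp(-eff.a * x_team) - params.k)
    return EquilibriumResult(
        kind="team_optimum",
        v_star=v_team,
        v_star_total=x_team,
        payoff=fitness(profile, params, scaling),
        residual=residual,
        curvature=None,
        N=N,
        scaling=scaling,
    )


def competitiveness(
    params: ModelParams,
    N: int,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Per-cell transporter excess of the ESS over the team optimum.

    The gap measures how strongly cells engage in the tragedy of the
    commons; it is zero at N = 1 and grows with neighborhood size.
    """
    ess = solve_ess(params, N, scaling)
    team = solve_team_optimum(params, N, scaling)
    return ess.v_star - team.v_star


def sweep_N(
    params: ModelParams,
    N_values: Iterable[int],
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> list[tuple[EquilibriumResult, EquilibriumResult]]:
    """Solve (ESS, team optimum) for each neighborhood size in ``N_values``."""
    scaling = ScalingAssumption.coerce(scaling)
    values: Sequence[int] = list(N_values)
    if not values:
        raise ValueError("N_values must be nonempty")
    return [
        (solve_ess(params, N, scaling), solve_team_optimum(params, N, scaling))
        for N in values
    ]
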