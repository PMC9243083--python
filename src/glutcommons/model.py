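"""Fitness-generating function for transporter-mediated nutrient competition.

A focal cancer cell carrying ``v`` glucose transporters competes with the
``N - 1`` other cells of its depletion zone (the area over which a cell can
access and deplete nutrients).  The neighborhood's collective uptake rate
saturates with the total transporter count ``x``,

    phi(x) = R * (1 - exp(-a * x)),

and the focal cell harvests its proportional share ``v / x`` of that uptake
while paying a linear production/maintenance cost ``k * v``:

    G(v, u, N) = (v / x) * phi(x) - k * v,      x = v + (N - 1) * u.

``R`` is resource (glucose) availability per depletion zone, ``a`` the
per-transporter encounter rate with the resource, and ``k`` the cost of one
transporter — all in abstract resource-units-per-time and transporter units.

Two scaling rules describe how the microenvironment changes with ``N``:
under *crowding* the depletion zone is fixed and ``R``, ``a`` are unchanged;
under the *depletion-zone* rule the zone grows with ``N`` at fixed cell
density, so ``R(N) = R*N`` and ``a(N) = a/N`` (resources per cell constant).

First and second derivatives of G with respect to ``v`` are implemented
analytically from the G-function itself (with effective parameters), so they
are valid at any profile, not only at the symmetric point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "ModelParams",
    "ScalingAssumption",
    "StrategyProfile",
    "BASELINE_PARAMS",
    "effective_params",
    "gain",
    "cost",
    "fitness",
    "fitness_gradient",
    "fitness_curvature",
]


@dataclass(frozen=True)
class ModelParams:
    """Environmental and economic constants of the transporter game.

    Parameters
    ----------
    R : float
        Resource availability (resource units per time, per reference
        depletion zone).  Must be positive.
    a : float
        Per-transporter encounter rate with the resource (1/transporter).
        Must be positive.
    k : float
        Cost of producing and maintaining one transporter (resource units
        per time per transporter).  Must be positive.

    Notes
    -----
    A positive equilibrium exists only when ``k < R * a`` (the marginal
    value of the very first transporter must exceed its cost); the solvers
    enforce this, not the container.
    """

    R: float
    a: float
    k: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.a > 0 and self.k > 0):
            raise ValueError(
                f"ModelParams requires R, a, k > 0; got R={self.R}, a={self.a}, k={self.k}"
            )

    @property
    def cost_ratio(self) -> float:
        """Dimensionless cost ratio k / (R * a); the game depends on (this, N)."""
        return self.k / (self.R * self.a)


#: Baseline parametrization used throughout the numerical experiments.
BASELINE_PARAMS = ModelParams(R=10_000.0, a=2e-6, k=0.0055)


class ScalingAssumption(str, enum.Enum):
    """How R and a transform with neighborhood size N.

    ``CROWDING``: depletion-zone size fixed, density varies; R and a are
    independent of N.  ``DEPLETION_ZONE``: density fixed, zone size varies;
    R(N) = R*N and a(N) = a/N, keeping resources per cell constant.
    """

    CROWDING = "crowding"
    DEPLETION_ZONE = "depletion_zone"

    @classmethod
    def coerce(cls, value: "ScalingAssumption | str") -> "ScalingAssumption":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("-", "_")
        try:
            return cls(key)
        except ValueError:
            raise ValueError(
                f"unknown scaling assumption {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def _check_N(N: int | float, *, allow_real: bool = False) -> float:
    if allow_real:
        if not (isinstance(N, (int, float)) and N >= 1 and math.isfinite(N)):
            raise ValueError(f"N must be a real number >= 1; got {N!r}")
        return float(N)
    if isinstance(N, float) and N.is_integer():
        N = int(N)
    if not isinstance(N, int) or isinstance(N, bool) or N < 1:
        raise ValueError(f"N must be an integer >= 1; got {N!r}")
    return float(N)


@dataclass(frozen=True)
class StrategyProfile:
    """Symmetric strategy profile of a depletion-zone neighborhood.

    ``v`` is the focal cell's transporter count, ``u`` the (common) resident
    transporter count of each of the ``N - 1`` competitors.  Residents are
    symmetric: every computation of interest evaluates at symmetric or
    unilaterally-deviating profiles.  When ``N == 1`` there are no residents
    and ``u`` is ignored.
    """

    v: float
    u: float = 0.0
    N: int = 1

    def __post_init__(self) -> None:
        if self.v < 0 or self.u < 0:
            raise ValueError(f"strategies must be nonnegative; got v={self.v}, u={self.u}")
        _check_N(self.N)

    @property
    def x(self) -> float:
        """Total transporters in the neighborhood, v + (N-1)*u."""
        return self.v + (self.N - 1) * self.u


def effective_params(
    params: ModelParams,
    N: int,
    scaling: ScalingAssumption | str,
) -> ModelParams:
    """Return the (R, a, k) effective in a neighborhood of ``N`` cells.

    Crowding leaves parameters untouched; the depletion-zone rule scales
    ``R -> R*N`` and ``a -> a/N``.  The per-transporter cost ``k`` never
    scales.  Note ``R*a`` — and hence the cost ratio ``k/(R*a)`` — is
    invariant under the depletion-zone rule.
    """
    scaling = ScalingAssumption.coerce(scaling)
    n = _check_N(N, allow_real=True)
    if scaling is ScalingAssumption.CROWDING or n == 1:
        return params
    return ModelParams(R=params.R * n, a=params.a / n, k=params.k)


def gain(x: float, params: ModelParams) -> float:
    """Collective uptake rate phi(x) = R * (1 - exp(-a*x)) of x transporters.

    Strictly increasing and concave in ``x``, saturating at ``R``:
    each additional transporter encounters only resource the others missed.
    """
    if x < 0:
        raise ValueError(f"transporter count must be nonnegative; got x={x}")
    return params.R * -math.expm1(-params.a * x)


def cost(v: float, params: ModelParams) -> float:
    """Linear production/maintenance cost k*v of carrying v transporters."""
    if v < 0:
        raise ValueError(f"transporter count must be nonnegative; got v={v}")
    return params.k * v


def fitness(
    profile: StrategyProfile,
    params: ModelParams,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Per-cell payoff G(v, u, N) = (v/x) * phi_eff(x) - k*v.

    The focal cell's share of the collective harvest is its transporter
    share ``v/x``.  At ``v = x = 0`` the payoff is 0 (no investment, no
    uptake, no cost; the share convention takes the v/x limit as full share
    of zero uptake, which keeps G continuous at the origin).
    """
    eff = effective_params(params, profile.N, scaling)
    x = profile.x
    if x == 0.0:
        return 0.0
    return (profile.v / x) * gain(x, eff) - eff.k * profile.v


def fitness_gradient(
    profile: StrategyProfile,
    params: ModelParams,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Marginal payoff dG/dv of one extra transporter on the focal cell.

    Differentiating G at fixed residents (dx/dv = 1):

        dG/dv = phi(x) * (x - v) / x**2  +  (v/x) * R*a*exp(-a*x)  -  k

    with effective R, a.  The first term is the focal cell's gain in *share*
    of the existing harvest, the second its share of the *marginal* harvest.
    At a symmetric profile under depletion-zone scaling (x = N*v,
    a_eff = a/N) the exponent collapses to exp(-a*v), recovering the
    symmetric-point form used to define the ESS condition.
    """
    eff = effective_params(params, profile.N, scaling)
    x = profile.x
    if x <= 0:
        raise ValueError("fitness_gradient requires a profile with x > 0")
    v = profile.v
    e = math.exp(-eff.a * x)
    share_term = gain(x, eff) * (x - v) / (x * x)
    marginal_term = (v / x) * eff.R * eff.a * e
    return share_term + marginal_term - eff.k


def fitness_curvature(
    profile: StrategyProfile,
    params: ModelParams,
    scaling: ScalingAssumption | str = ScalingAssumption.DEPLETION_ZONE,
) -> float:
    """Second derivative d2G/dv2 at fixed residents; negative at a fitness peak.

        d2G/dv2 = 2*(x - v)/x**2 * R*a*exp(-a*x)
                  - 2*phi(x)*(x - v)/x**3
                  - (v/x) * R*a**2*exp(-a*x)

    with effective R, a.
    """
    eff = effective_params(params, profile.N, scaling)
    x = profile.x
    if x <= 0:
        raise ValueError("fitness_curvature requires a profile with x > 0")
    v = profile.v
    e = math.exp(-eff.a * x)
    phi = gain(x, eff)
    return (
        2.0 * (x - v) / (x * x) * eff.R * eff.a * e
        - 2.0 * phi * (x - v) / (x * x * x)
        - (v / x) * eff.R * eff.a * eff.a * e
    )
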