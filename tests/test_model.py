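"""Core fitness function: gain/cost ingredients, derivatives, scalings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glutcommons import (
    ModelParams,
    ScalingAssumption,
    StrategyProfile,
    cost,
    effective_params,
    fitness,
    fitness_curvature,
    fitness_gradient,
    gain,
)

from conftest import random_game

DZ = ScalingAssumption.DEPLETION_ZONE
CR = ScalingAssumption.CROWDING


class TestParamsAndProfiles:
    @pytest.mark.parametrize("bad", [dict(R=0, a=1, k=1), dict(R=1, a=-1, k=1), dict(R=1, a=1, k=0)])
    def test_nonpositive_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_profile_totals_and_validation(self):
        p = StrategyProfile(v=3.0, u=2.0, N=4)
        assert p.x == 3.0 + 3 * 2.0
        assert StrategyProfile(v=5.0, N=1).x == 5.0
        with pytest.raises(ValueError):
            StrategyProfile(v=-1.0)
        with pytest.raises(ValueError):
            StrategyProfile(v=1.0, N=0)

    def test_scaling_coercion_accepts_hyphenated_names(self):
        assert ScalingAssumption.coerce("depletion-zone") is DZ
        assert ScalingAssumption.coerce("CROWDING") is CR
        with pytest.raises(ValueError):
            ScalingAssumption.coerce("isotropic")


class TestEffectiveParams:
    def test_depletion_zone_scales_R_up_and_a_down(self, baseline):
        eff = effective_params(baseline, 5, DZ)
        assert eff.R == pytest.approx(50_000.0)
        assert eff.a == pytest.approx(4e-7)
        assert eff.k == baseline.k  # the per-transporter cost never scales

    @pytest.mark.parametrize("scaling", [DZ, CR])
    def test_N1_is_identity(self, baseline, scaling):
        assert effective_params(baseline, 1, scaling) == baseline

    def test_crowding_leaves_params_unchanged(self, baseline):
        assert effective_params(baseline, 5, CR) == baseline

    def test_invalid_N_rejected(self, baseline):
        with pytest.raises(ValueError):
            effective_params(baseline, 0, DZ)

    def test_cost_ratio_invariant_under_depletion_zone(self, baseline):
        for N in (2, 7, 100):
            eff = effective_params(baseline, N, DZ)
            assert eff.k / (eff.R * eff.a) == pytest.approx(baseline.cost_ratio)


class TestGainAndCost:
    def test_gain_anchors(self, baseline):
        assert gain(0.0, baseline) == 0.0
        assert gain(math.log(2) / baseline.a, baseline) == pytest.approx(baseline.R / 2)
        assert gain(1e12, baseline) == pytest.approx(baseline.R)

    def test_gain_monotone_concave_bounded(self, baseline):
        x = np.linspace(0.0, 5.0 / baseline.a, 1000)
        y = np.array([gain(xi, baseline) for xi in x])
        assert np.all(np.diff(y) > 0)
        assert np.all(np.diff(y, 2) < 0)
        assert np.all(y <= baseline.R)

    def test_cost_is_linear(self, baseline):
        assert cost(0.0, baseline) == 0.0
        assert cost(1.0, baseline) == baseline.k
        assert cost(645_492.0, baseline) == pytest.approx(3550.206)

    def test_negative_inputs_rejected(self, baseline):
        with pytest.raises(ValueError):
            gain(-1.0, baseline)
        with pytest.raises(ValueError):
            cost(-1.0, baseline)


class TestFitness:
    def test_zero_investment_zero_payoff(self, baseline):
        assert fitness(StrategyProfile(v=0.0, u=0.0, N=3), baseline, DZ) == 0.0
        # free-riding on residents: zero cost, zero share
        assert fitness(StrategyProfile(v=0.0, u=1e5, N=3), baseline, DZ) == 0.0

    def test_symmetric_payoffs_match_reference_table(self, baseline):
        solo = fitness(StrategyProfile(v=645_492.0, u=645_492.0, N=1), baseline, DZ)
        crowd = fitness(StrategyProfile(v=1_430_884.0, u=1_430_884.0, N=5), baseline, DZ)
        assert solo == pytest.approx(3700, abs=0.5)
        assert crowd == pytest.approx(1558, abs=0.5)

    def test_per_cell_uptake_independent_of_N_under_depletion_zone(self, baseline):
        # With R*N and a/N, N*phi(v) == phi(x): uptake per cell at a fixed
        # per-cell strategy does not depend on neighborhood size.
        v = 4e5
        ref = fitness(StrategyProfile(v=v, u=v, N=1), baseline, DZ)
        for N in (2, 5, 10, 100):
            val = fitness(StrategyProfile(v=v, u=v, N=N), baseline, DZ)
            assert val == pytest.approx(ref, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, baseline, c):
        # (R, a) -> (cR, a/c) keeps k/(R*a) fixed and rescales both the
        # natural strategy unit and the payoff by c.
        scaled = ModelParams(R=c * baseline.R, a=baseline.a / c, k=baseline.k)
        for N in (1, 4):
            v = 3e5
            base = fitness(StrategyProfile(v=v, u=v, N=N), baseline, DZ)
            big = fitness(StrategyProfile(v=c * v, u=c * v, N=N), scaled, DZ)
            assert big == pytest.approx(c * base, rel=1e-12)


def _fd_gradient(profile, params, scaling, h):
    up = StrategyProfile(v=profile.v + h, u=profile.u, N=profile.N)
    dn = StrategyProfile(v=profile.v - h, u=profile.u, N=profile.N)
    return (fitness(up, params, scaling) - fitness(dn, params, scaling)) / (2 * h)


def _fd_curvature(profile, params, scaling, h):
    up = StrategyProfile(v=profile.v + h, u=profile.u, N=profile.N)
    dn = StrategyProfile(v=profile.v - h, u=profile.u, N=profile.N)
    mid = fitness(profile, params, scaling)
    return (fitness(up, params, scaling) - 2 * mid + fitness(dn, params, scaling)) / (h * h)


class TestDerivatives:
    def test_gradient_matches_finite_difference_at_fixed_point(self, baseline):
        profile = StrategyProfile(v=3e5, u=2e5, N=4)
        h = 1e-3 * profile.v
        for scaling in (DZ, CR):
            fd = _fd_gradient(profile, baseline, scaling, h)
            assert fitness_gradient(profile, baseline, scaling) == pytest.approx(fd, rel=1e-6)

    def test_derivatives_match_finite_differences_on_random_draws(self, rng):
        for _ in range(100):
            params, N = random_game(rng)
            scale = 1.0 / params.a
            v = rng.uniform(0.05, 3.0) * scale
            u = rng.uniform(0.05, 3.0) * scale
            profile = StrategyProfile(v=v, u=u, N=N)
            scaling = DZ if rng.random() < 0.5 else CR
            h = 1e-4 * profile.x
            fd_g = _fd_gradient(profile, params, scaling, h)
            fd_c = _fd_curvature(profile, params, scaling, h)
            # Near stationary points the gradient itself vanishes, so the
            # comparison is made relative to the natural scales R*a (gradient)
            # and R*a^2 (curvature) rather than the value alone.
            g_scale = params.R * params.a
            c_scale = params.R * params.a**2
            assert fitness_gradient(profile, params, scaling) == pytest.approx(
                fd_g, rel=1e-6, abs=1e-6 * g_scale
            )
            assert fitness_curvature(profile, params, scaling) == pytest.approx(
                fd_c, rel=1e-4, abs=1e-4 * c_scale
            )

    def test_first_transporter_has_positive_net_value(self, baseline):
        g = fitness_gradient(StrategyProfile(v=1e-9, u=0.0, N=1), baseline, DZ)
        assert g == pytest.approx(baseline.R * baseline.a - baseline.k, rel=1e-6)
        assert g > 0

    def test_symmetric_depletion_zone_gradient_uses_av_exponent(self, baseline):
        # At v = u under depletion-zone scaling the general gradient must
        # collapse to the symmetric-point form
        #   (R*a/N)*exp(-a*v) + ((N-1)/N)*R*(1-exp(-a*v))/v - k,
        # whose exponent depends on the per-cell strategy alone.
        R, a, k = baseline.R, baseline.a, baseline.k
        for N in (1, 2, 5, 10, 100):
            for v in (1e5, 645_492.0, 2e6):
                sym = (R * a / N) * math.exp(-a * v) + (N - 1) / N * R * (
                    -math.expm1(-a * v)
                ) / v - k
                grad = fitness_gradient(StrategyProfile(v=v, u=v, N=N), baseline, DZ)
                assert grad == pytest.approx(sym, rel=1e-10, abs=1e-15)

    def test_zero_total_transporters_rejected(self, baseline):
        with pytest.raises(ValueError):
            fitness_gradient(StrategyProfile(v=0.0, u=0.0, N=2), baseline, DZ)
        with pytest.raises(ValueError):
            fitness_curvature(StrategyProfile(v=0.0, u=0.0, N=2), baseline, DZ)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    x1=st.floats(min_value=0.0, max_value=5e6),
    x2=st.floats(min_value=0.0, max_value=5e6),
)
def test_gain_monotone_and_bounded_property(x1, x2):
    params = ModelParams(R=10_000.0, a=2e-6, k=0.0055)
    lo, hi = sorted((x1, x2))
    assert gain(lo, params) <= gain(hi, params) <= params.R
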