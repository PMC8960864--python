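"""Unit tests of the instantaneous rate equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firecycle import (
    InvalidStateError,
    ModelParams,
    PolicyConfig,
    SystemState,
    burn_rate,
    derivatives,
    empty_area,
    flammable_burn_fraction,
    human_ignition,
    perception_rate,
    property_rate,
    strong_burn_fraction,
    vulnerability_rate,
)


class TestEmptyArea:
    @pytest.mark.parametrize(
        "S,F,expected", [(0.5, 0.4, 0.1), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0)]
    )
    def test_budget(self, S, F, expected):
        assert empty_area(S, F) == pytest.approx(expected)

    def test_rejects_overfull_forest(self):
        with pytest.raises(InvalidStateError):
            empty_area(0.7, 0.5)
        with pytest.raises(InvalidStateError):
            empty_area(-0.2, 0.5)


class TestFlammableBurnFraction:
    def test_no_ignition_no_burn(self):
        assert flammable_burn_fraction(0.0, 0.0, 1.0) == 0.0

    def test_linear_closure_at_initial_ignitions(self):
        assert flammable_burn_fraction(0.3, 0.5, 1.0) == pytest.approx(0.8)

    @given(
        i_h=st.floats(0, 5), i_n=st.floats(0, 5), c=st.floats(0.01, 3)
    )
    @settings(max_examples=50, deadline=None)
    def test_doubling_total_ignition_doubles_burn(self, i_h, i_n, c):
        assert flammable_burn_fraction(2 * i_h, 2 * i_n, c) == pytest.approx(
            2 * flammable_burn_fraction(i_h, i_n, c)
        )


class TestStrongBurnFraction:
    def test_sigmoid_midpoint_is_half_ceiling(self, base_params):
        # gamma_F * F == n puts the sigmoid at gamma_max / 2
        assert strong_burn_fraction(1.0, base_params.n, base_params) == pytest.approx(0.4)

    def test_vanishing_fire_approaches_sigmoid_offset(self, base_params):
        # direct evaluation of the sigmoid as gamma_F * F -> 0+
        expected = 0.8 / (1.0 + math.exp(5.0))
        assert strong_burn_fraction(1e-12, 0.4, base_params) == pytest.approx(expected)
        assert expected == pytest.approx(5.3585e-3, rel=1e-3)

    def test_no_surface_fire_means_no_propagation(self, base_params):
        # the propagation gate closes the fire-free limit exactly
        assert strong_burn_fraction(0.0, 0.4, base_params) == 0.0
        assert strong_burn_fraction(0.3, 0.0, base_params) == 0.0

    def test_approaches_ceiling_from_below(self, base_params):
        big = strong_burn_fraction(0.5, 1.0, base_params)
        assert big < base_params.gamma_max
        assert big == pytest.approx(base_params.gamma_max, rel=1e-6)

    @given(x=st.floats(0, 5), y=st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, x, y):
        p = ModelParams()
        lo, hi = sorted([x, y])
        g_lo = strong_burn_fraction(lo, 1.0, p)
        g_hi = strong_burn_fraction(hi, 1.0, p)
        assert 0.0 <= g_lo <= g_hi <= p.gamma_max


class TestBurnRate:
    def test_additive_over_vegetation_classes(self):
        assert burn_rate(0.0, 0.4, 0.0, 0.5) == 0.0
        assert burn_rate(0.3, 0.4, 0.01, 0.5) == pytest.approx(0.125)
        assert burn_rate(0.3, 0.4, 0.0, 0.0) + burn_rate(0.0, 0.0, 0.01, 0.5) == (
            pytest.approx(burn_rate(0.3, 0.4, 0.01, 0.5))
        )


class TestVulnerabilityRate:
    def test_linear_in_burn(self):
        assert vulnerability_rate(0.0, 0.05) == 0.0
        assert vulnerability_rate(0.2, 0.05) == pytest.approx(0.01)
        assert vulnerability_rate(0.4, 0.05) == pytest.approx(2 * vulnerability_rate(0.2, 0.05))


class TestHumanIgnition:
    def test_initial_anchor(self, base_params):
        # h0 is derived so the initial state reproduces the configured level
        got = human_ignition(base_params.v0, base_params.bbar0, base_params)
        assert got == pytest.approx(base_params.ih0)

    def test_perception_floor(self, base_params):
        huge = 2.0 / base_params.ignition_sensitivity
        assert human_ignition(base_params.v0, huge, base_params) == 0.0

    def test_proportional_to_settlement(self, base_params):
        one = human_ignition(0.3, 0.1, base_params)
        assert human_ignition(0.6, 0.1, base_params) == pytest.approx(2 * one)


class TestPerceptionRate:
    def test_fixed_point_and_arithmetic(self):
        assert perception_rate(0.1, 0.1, 0.5) == 0.0
        assert perception_rate(0.2, 0.1, 0.5) == pytest.approx(0.2)

    def test_relaxes_to_constant_burn(self):
        # analytic solution of the first-order lag under constant B
        B, delta1 = 0.3, 1.0
        bbar = 0.0
        dt = 0.01
        for _ in range(4000):
            bbar += dt * perception_rate(B, bbar, delta1)
        assert bbar == pytest.approx(B, rel=1e-6)


class TestPropertyRate:
    def test_zero_is_absorbing(self, base_params):
        assert property_rate(0.0, 0.5, 0.5, base_params) == 0.0

    def test_equilibrium_when_development_balances_demolition(self, base_params):
        p = base_params
        # pick Bbar so theta * (1 - k Bbar) == rho0 + d * B at B = 0
        bbar = (1.0 - p.demolition_base / p.dev_propensity) / p.dev_sensitivity
        assert property_rate(0.4, bbar, 0.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_growth_sign_without_fire(self, base_params):
        p = base_params
        assert p.dev_propensity > p.demolition_base
        assert property_rate(0.4, 0.0, 0.0, p) > 0.0


class TestDerivatives:
    def test_no_ignition_reduces_to_succession(self, firefree_params):
        state = SystemState(S=0.5, F=0.4, V=0.4, Bbar=0.0)
        rates = derivatives(state, firefree_params)
        p = firefree_params
        assert rates.dS == pytest.approx(state.F / p.tau1)
        assert rates.dF == pytest.approx((1 - 0.5 - 0.4) / p.tau2 - state.F / p.tau1)
        assert rates.dcumB == 0.0

    def test_matches_independent_evaluation_at_initials(self, base_params):
        """Transcribe the model equations independently and compare."""
        p = base_params
        state = p.initial_state()
        S, F, V, Bbar = state.S, state.F, state.V, state.Bbar
        i_h = p.h0 * (V / p.v0) * max(0.0, 1.0 - p.ignition_sensitivity * Bbar)
        gamma_f = p.burn_per_ignition * (i_h + p.i_n)
        gamma_s = p.gamma_max / (1.0 + math.exp(-p.steepness * (gamma_f * F / p.n - 1.0)))
        B = gamma_f * F + gamma_s * S
        alpha = p.sigma * B
        expected_dS = F / p.tau1 - (alpha + gamma_s) * S
        expected_dF = (1 - S - F) / p.tau2 + alpha * S - (1.0 / p.tau1 + gamma_f) * F
        expected_dV = V * (
            p.dev_propensity * max(0.0, 1.0 - p.dev_sensitivity * Bbar)
            - (p.demolition_base + p.demolition_fire * B)
        )
        expected_dBbar = (B - Bbar) / p.delta1
        rates = derivatives(state, p)
        assert rates.dS == pytest.approx(expected_dS, rel=1e-12)
        assert rates.dF == pytest.approx(expected_dF, rel=1e-12)
        assert rates.dV == pytest.approx(expected_dV, rel=1e-12)
        assert rates.dBbar == pytest.approx(expected_dBbar, rel=1e-12)
        assert rates.dcumB == pytest.approx(B, rel=1e-12)

    @pytest.mark.parametrize(
        "policy",
        [None, PolicyConfig(p1=True), PolicyConfig(p2=True, p3=True),
         PolicyConfig(p1=True, p2=True, p3=True, p4=True)],
        ids=["none", "p1", "p2p3", "all"],
    )
    @given(
        S=st.floats(0.0, 0.9),
        frac=st.floats(0.0, 1.0),
        V=st.floats(0.0, 2.0),
        Bbar=st.floats(0.0, 1.0),
        t=st.floats(0.0, 20.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_area_rate_conservation(self, policy, S, frac, V, Bbar, t):
        """dS + dF + dE = 0 at every state, with and without policies."""
        F = frac * (1.0 - S)
        state = SystemState(S=S, F=F, V=V, Bbar=Bbar)
        rates = derivatives(state, ModelParams(), policy, t)
        dE = -rates.dS - rates.dF  # E = 1 - S - F by construction
        assert rates.dS + rates.dF + dE == 0.0

    def test_rejects_invalid_state(self, base_params):
        with pytest.raises(InvalidStateError):
            derivatives(SystemState(S=0.9, F=0.4, V=0.4, Bbar=0.0), base_params)
        with pytest.raises(InvalidStateError):
            derivatives(SystemState(S=0.5, F=0.4, V=-1.0, Bbar=0.0), base_params)
        with pytest.raises(InvalidStateError):
            derivatives(base_params.initial_state(), base_params, None, t=-1.0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("tau1", 0.0), ("tau2", -1.0), ("delta1", 0.0), ("gamma_max", 1.5),
         ("n", 0.0), ("sigma", -0.1)],
    )
    def test_invalid_values_rejected(self, field, value):
        from firecycle.errors import ConfigError

        with pytest.raises(ConfigError):
            ModelParams(**{field: value})

    def test_overfull_initial_vegetation_rejected(self):
        from firecycle.errors import ConfigError

        with pytest.raises(ConfigError):
            ModelParams(s0=0.7, f0=0.5)
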