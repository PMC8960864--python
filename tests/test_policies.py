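"""Policy levers: Table-style operationalization, composition, conservation."""

import numpy as np
import pytest

from firecycle import (
    ConfigError,
    ModelParams,
    PolicyConfig,
    derivatives,
    integrate,
    strong_burn_fraction,
)
from firecycle.policies import apply_policies


@pytest.fixture(scope="module")
def state_at_year5(base_params):
    traj = integrate(base_params, horizon=5.0, dt=1.0 / 64.0)
    return traj.at(5.0)


class TestApplyPolicies:
    def test_all_flags_off_is_identity(self, base_params, state_at_year5):
        rates = derivatives(state_at_year5, base_params)
        assert apply_policies(rates, state_at_year5, base_params, PolicyConfig(), 6.0) is rates
        assert apply_policies(rates, state_at_year5, base_params, None, 6.0) is rates

    def test_inactive_before_start_time(self, base_params, state_at_year5):
        rates = derivatives(state_at_year5, base_params)
        policy = PolicyConfig(p1=True, p2=True, p3=True, p4=True, start_time=5.0)
        assert apply_policies(rates, state_at_year5, base_params, policy, 4.99) is rates

    def test_p2_diverts_exactly_omega_f(self, base_params, state_at_year5):
        rates = derivatives(state_at_year5, base_params)
        policy = PolicyConfig(p2=True, omega=0.2, start_time=5.0)
        treated = apply_policies(rates, state_at_year5, base_params, policy, 5.0)
        assert treated.dF == pytest.approx(rates.dF - 0.2 * state_at_year5.F, rel=1e-12)
        assert treated.dS == pytest.approx(rates.dS)  # flow goes to empty area
        # implied dE gains exactly what F loses
        dE_base = -rates.dS - rates.dF
        dE_treated = -treated.dS - treated.dF
        assert dE_treated - dE_base == pytest.approx(0.2 * state_at_year5.F, rel=1e-12)

    def test_p3_scales_strong_burn_to_ten_percent(self, base_params, state_at_year5):
        """The firefighting lever multiplies the sigmoid gamma_S by 0.1
        before it enters both the vegetation and burn-rate equations."""
        from firecycle.model import instantaneous

        policy = PolicyConfig(p3=True, firefight_factor=0.1, start_time=5.0)
        plain = instantaneous(state_at_year5.as_tuple(), base_params, None, 5.0)
        treated = instantaneous(state_at_year5.as_tuple(), base_params, policy, 5.0)
        assert treated.gamma_s == pytest.approx(0.1 * plain.gamma_s, rel=1e-12)
        expected_B = plain.gamma_f * state_at_year5.F + 0.1 * plain.gamma_s * state_at_year5.S
        assert treated.B == pytest.approx(expected_B, rel=1e-12)

    def test_p4_direct_variant_feeds_flammable_stock(self, base_params, state_at_year5):
        """With the direct routing, clear cutting is the only lever that
        increases the instantaneous flammable inflow."""
        rates = derivatives(state_at_year5, base_params)
        policy = PolicyConfig(p4=True, vartheta=0.2, start_time=5.0, p4_to_empty=False)
        treated = apply_policies(rates, state_at_year5, base_params, policy, 5.0)
        assert treated.dF > rates.dF
        assert treated.dF == pytest.approx(rates.dF + 0.2 * state_at_year5.S, rel=1e-12)
        assert treated.dS == pytest.approx(rates.dS - 0.2 * state_at_year5.S, rel=1e-12)

    def test_p4_default_clears_to_empty_ground(self, base_params, state_at_year5):
        rates = derivatives(state_at_year5, base_params)
        policy = PolicyConfig(p4=True, vartheta=0.2, start_time=5.0)
        assert policy.p4_to_empty  # cleared area becomes empty ground
        treated = apply_policies(rates, state_at_year5, base_params, policy, 5.0)
        assert treated.dS == pytest.approx(rates.dS - 0.2 * state_at_year5.S, rel=1e-12)
        assert treated.dF == pytest.approx(rates.dF)  # outflow bypasses F

    def test_p4_raises_flammable_vegetation_over_time(self, base_params, base_traj):
        """Clear cutting ends up increasing the flammable stock through
        regrowth of the cleared ground."""
        policy = PolicyConfig(p4=True, start_time=5.0)
        treated = integrate(base_params, policy=policy, horizon=20.0, dt=1.0 / 32.0)
        base = integrate(base_params, horizon=20.0, dt=1.0 / 32.0)
        late = base.t >= 10.0
        assert np.mean(treated.F[late]) > np.mean(base.F[late])

    def test_p1_fixes_development_rate(self, base_params, state_at_year5):
        policy = PolicyConfig(p1=True, dev_rate_cap=0.01, start_time=5.0)
        rates = derivatives(state_at_year5, base_params, policy, 5.0)
        p = base_params
        V, B = state_at_year5.V, None
        from firecycle.model import instantaneous

        inst = instantaneous(state_at_year5.as_tuple(), base_params, policy, 5.0)
        expected = V * (0.01 - (p.demolition_base + p.demolition_fire * inst.B))
        assert rates.dV == pytest.approx(expected, rel=1e-12)


class TestPolicyTrajectories:
    def test_identical_before_start_time(self, base_params, base_traj):
        policy = PolicyConfig(p1=True, p2=True, p3=True, p4=True, start_time=5.0)
        treated = integrate(base_params, policy=policy, horizon=20.0, dt=1.0 / 64.0)
        before = base_traj.t < 5.0
        for name in ("S", "F", "V", "Bbar", "B"):
            assert np.array_equal(
                treated.series(name)[before], base_traj.series(name)[before]
            )
        # and they must differ afterwards
        assert not np.allclose(treated.B[-10:], base_traj.B[-10:])

    @pytest.mark.parametrize("levers", [("p2",), ("p4",), ("p1", "p2", "p3", "p4")])
    def test_conservation_under_policy(self, base_params, levers):
        policy = PolicyConfig.combo(*levers)
        traj = integrate(base_params, policy=policy, horizon=20.0, dt=1.0 / 32.0)
        assert np.max(np.abs(traj.S + traj.F + traj.E - 1.0)) < 1e-9


class TestPolicyConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(omega=1.5), dict(vartheta=-0.1), dict(firefight_factor=0.0),
         dict(firefight_factor=1.2), dict(dev_rate_cap=-0.01), dict(start_time=-1.0)],
    )
    def test_invalid_intensities_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PolicyConfig(**kwargs)

    def test_combo_builder(self):
        policy = PolicyConfig.combo("p1", "p3")
        assert policy.p1 and policy.p3 and not policy.p2 and not policy.p4
        assert policy.label == "P1+P3"
        with pytest.raises(ConfigError):
            PolicyConfig.combo("p9")
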