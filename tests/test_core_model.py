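"""Parameter container, rate functions, terminal reward, and the one-step kernel."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import playsdp as ps
from playsdp import FORAGE, PLAY, REST
from conftest import mini_config


class TestLinearAbilityMap:
    @pytest.mark.parametrize(
        "a, v0, vA, A, expected",
        [
            (0, 0.005, 0.0002, 100, 0.005),      # low-ability forager at full risk
            (100, 0.1, 0.9, 100, 0.9),           # expert forager at max success
            (50, 0.005, 0.0002, 100, 0.0026),    # linear midpoint
            (25, 0.0, 1.0, 100, 0.25),
        ],
    )
    def test_endpoint_and_midpoint_values(self, a, v0, vA, A, expected):
        assert ps.linear_ability_map(a, v0, vA, A) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_ability_rejected(self):
        with pytest.raises(ValueError):
            ps.linear_ability_map(-1, 0.0, 1.0, 100)
        with pytest.raises(ValueError):
            ps.linear_ability_map(101, 0.0, 1.0, 100)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.integers(0, 100), v0=st.floats(0, 1), vA=st.floats(0, 1))
    def test_stays_between_endpoints(self, a, v0, vA):
        val = ps.linear_ability_map(a, v0, vA, 100)
        assert min(v0, vA) - 1e-12 <= val <= max(v0, vA) + 1e-12


class TestTerminalReward:
    def test_below_critical_reserves_scores_zero(self):
        cfg = ps.ModelConfig.for_variant("model1")
        assert ps.terminal_reward(149, 0, cfg) == 0.0
        assert ps.terminal_reward(149, 100, cfg) == 0.0

    def test_binary_payoff_at_default_exponent(self):
        cfg = ps.ModelConfig.for_variant("model1")
        assert ps.terminal_reward(150, 0, cfg) == 1.0
        assert ps.terminal_reward(300, 50, cfg) == 1.0

    def test_reproduction_probability_scales_payoff(self):
        cfg = ps.ModelConfig.for_variant("model3a")
        assert ps.terminal_reward(300, 0, cfg) == pytest.approx(0.1)
        assert ps.terminal_reward(300, 100, cfg) == pytest.approx(0.9)
        assert ps.terminal_reward(300, 50, cfg) == pytest.approx(0.5)

    def test_reserve_exponent_discounts_partial_surplus(self):
        cfg = ps.ModelConfig.for_variant("model1", q=1.0)
        assert ps.terminal_reward(150, 0, cfg) == pytest.approx(0.5)
        assert ps.terminal_reward(300, 0, cfg) == pytest.approx(1.0)

    def test_out_of_range_reserves_rejected(self):
        cfg = ps.ModelConfig.for_variant("model1")
        with pytest.raises(ValueError):
            ps.terminal_reward(301, 0, cfg)


class TestTransitionDistribution:
    def test_forage_outcome_tree_with_constant_rates(self):
        # Constant y_z = 0.7 and m_f = 0.002 with practice s_f = 0.8.
        cfg = ps.ModelConfig.for_variant("model3b")
        dist = ps.transition_distribution(ps.State(100, 0, 60), FORAGE, cfg)
        probs = {(xn, an): p for xn, an, p in dist.branches}
        assert probs[(103, 1)] == pytest.approx((1 - 0.002) * 0.7 * 0.8, abs=1e-12)
        assert probs[(103, 0)] == pytest.approx((1 - 0.002) * 0.7 * 0.2, abs=1e-12)
        assert probs[(98, 1)] == pytest.approx((1 - 0.002) * 0.3 * 0.8, abs=1e-12)
        assert probs[(98, 0)] == pytest.approx((1 - 0.002) * 0.3 * 0.2, abs=1e-12)
        assert dist.death_probability == pytest.approx(0.002, abs=1e-12)

    def test_rest_is_a_single_deterministic_branch(self):
        cfg = ps.ModelConfig.for_variant("model1")
        dist = ps.transition_distribution(ps.State(100, 5, 60), REST, cfg)
        assert dist.branches == [(99, 5, pytest.approx(1 - 0.0001, abs=1e-12))]
        assert dist.death_probability == pytest.approx(0.0001, abs=1e-12)

    def test_playing_at_the_cost_margin_starves_with_certainty(self):
        cfg = ps.ModelConfig.for_variant("model1")
        dist = ps.transition_distribution(ps.State(3, 0, 60), PLAY, cfg)
        assert dist.branches == []
        assert dist.death_probability == pytest.approx(1.0, abs=1e-12)

    def test_provisioning_can_rescue_from_starvation(self):
        cfg = ps.ModelConfig.for_variant("model1")
        dist = ps.transition_distribution(ps.State(1, 0, 0), REST, cfg)
        probs = {(xn, an): p for xn, an, p in dist.branches}
        # Rest costs 1; only a successful provision (w_e = 3) keeps x above 0.
        assert probs == {(3, 0): pytest.approx((1 - 0.0001) * 0.7, abs=1e-12)}
        assert dist.death_probability == pytest.approx(0.0001 + (1 - 0.0001) * 0.3, abs=1e-12)

    def test_usage_errors(self):
        cfg = ps.ModelConfig.for_variant("model1")
        with pytest.raises(ValueError):
            ps.transition_distribution(ps.State(0, 0, 0), REST, cfg)
        with pytest.raises(ValueError):
            ps.transition_distribution(ps.State(100, 0, cfg.T), REST, cfg)

    @settings(derandomize=True, max_examples=120)
    @given(
        variant=st.sampled_from(ps.VARIANTS),
        x=st.integers(1, 20),
        a=st.integers(0, 3),
        t=st.integers(0, 9),
        action=st.sampled_from([FORAGE, PLAY, REST]),
    )
    def test_kernel_is_a_probability_distribution(self, variant, x, a, t, action):
        cfg = mini_config(variant)
        dist = ps.transition_distribution(ps.State(x, a, t), action, cfg)
        assert dist.total() == pytest.approx(1.0, abs=1e-12)
        for xn, an, p in dist.branches:
            assert p >= 0
            assert 1 <= xn <= cfg.X
            assert an in (a, min(a + 1, cfg.A))
        assert dist.death_probability >= 0

    def test_ability_endpoints_hit_exactly(self):
        m1 = ps.ModelConfig.for_variant("model1")
        assert m1.forage_mortality(m1.A) == m1.m_p
        m2 = ps.ModelConfig.for_variant("model2")
        assert m2.forage_success(m2.A) == 0.9

    def test_zero_provisioning_probability_matches_no_provisioning_phase(self):
        # With w_z = 0 the kernel is identical whether the provisioning
        # window is maximal or minimal: the provision branch never fires.
        a = mini_config("model1", w_z=0.0, tau=10)
        b = mini_config("model1", w_z=0.0, tau=1)
        for x in range(1, a.X + 1):
            for ab in range(a.A + 1):
                for action in (FORAGE, PLAY, REST):
                    da = ps.transition_distribution(ps.State(x, ab, 3), action, a)
                    db = ps.transition_distribution(ps.State(x, ab, 3), action, b)
                    assert da.branches == db.branches
                    assert da.death_probability == db.death_probability

    @pytest.mark.parametrize("action", [FORAGE, PLAY, REST])
    def test_richer_states_stochastically_dominate(self, action):
        # The surviving next-energy distribution from x+1 dominates that
        # from x: more reserves never hurt.
        cfg = mini_config("model2")
        for x in range(4, cfg.X):
            for a in range(cfg.A + 1):
                lo = ps.transition_distribution(ps.State(x, a, 7), action, cfg)
                hi = ps.transition_distribution(ps.State(x + 1, a, 7), action, cfg)

                def survival_cdf(dist):
                    # P(x' <= v, survive) for all v; death mass excluded.
                    cdf = np.zeros(cfg.X + 2)
                    for xn, _, p in dist.branches:
                        cdf[xn] += p
                    return np.cumsum(cdf)

                assert (survival_cdf(hi) <= survival_cdf(lo) + 1e-12).all()


class TestModelConfig:
    def test_variant_defaults(self):
        m1 = ps.ModelConfig.for_variant("model1")
        assert (m1.m_f0, m1.m_fA) == (0.005, m1.m_p)
        m2 = ps.ModelConfig.for_variant("model2")
        assert (m2.y_z0, m2.y_zA) == (0.1, 0.9)
        m3a = ps.ModelConfig.for_variant("model3a")
        assert m3a.s_f == 0.0
        m3b = ps.ModelConfig.for_variant("model3b")
        assert m3b.s_f > m3b.s_p

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            ps.ModelConfig.for_variant("model1", x_crit=400)
        with pytest.raises(ValueError):
            ps.ModelConfig.for_variant("model1", tau=300)
        with pytest.raises(ValueError):
            ps.ModelConfig.for_variant("model1", w_z=1.5)
        with pytest.raises(ValueError):
            ps.ModelConfig.for_variant("nomodel")
        with pytest.raises(ValueError):
            ps.ModelConfig.for_variant("model1", no_such_param=1)

    def test_negative_rest_cost_allowed(self):
        cfg = ps.ModelConfig.for_variant("model3a", c_r=-1)
        assert cfg.c_r == -1

    def test_advisory_orderings_warn_not_raise(self):
        with pytest.warns(ps.ConfigWarning):
            ps.ModelConfig.for_variant("model1", c_f=4)  # c_f > c_p
        with pytest.warns(ps.ConfigWarning):
            ps.ModelConfig.for_variant("model1", m_r=0.01)  # m_r > m_p

    def test_with_param_keeps_model1_mortality_coupling(self):
        cfg = ps.ModelConfig.for_variant("model1")
        swept = cfg.with_param("m_p", 0.001)
        assert swept.m_p == 0.001 and swept.m_fA == 0.001
        swept = cfg.with_param("m_f0", 0.0012)
        assert swept.m_f0 == 0.0012 and swept.m_fA == cfg.m_p

    def test_with_param_aliases_set_both_endpoints(self):
        cfg = ps.ModelConfig.for_variant("model3a")
        assert dataclasses.astuple(cfg.with_param("m_f", 0.01))  # no error
        swept = cfg.with_param("m_f", 0.01)
        assert (swept.m_f0, swept.m_fA) == (0.01, 0.01)
        swept = cfg.with_param("y_z", 0.4)
        assert (swept.y_z0, swept.y_zA) == (0.4, 0.4)

    def test_with_param_rejects_unknown(self):
        cfg = ps.ModelConfig.for_variant("model1")
        with pytest.raises(ValueError):
            cfg.with_param("variant", "model2")
        with pytest.raises(ValueError):
            cfg.with_param("bogus", 1)
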