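"""Shared fixtures: miniature model instances, full solved variants, and an
independent scalar recursion used as the value-function oracle."""

from __future__ import annotations

import numpy as np
import pytest

import playsdp as ps

# Miniature grid used wherever exactness, not scale, is under test.
MINI = dict(X=20, A=3, T=10, tau=5, x_crit=10)


def mini_config(variant: str, **overrides) -> ps.ModelConfig:
    params = dict(MINI)
    params.update(overrides)
    return ps.ModelConfig.for_variant(variant, **params)


def oracle_value(cfg: ps.ModelConfig, x: int, a: int, t: int, memo=None) -> float:
    """Exhaustive-expectation optimal value by plain scalar recursion.

    Re-derives every rate and transition from the parameters directly,
    independent of the package's kernel enumeration and of the vectorised
    induction; memoised on states only.
    """
    if memo is None:
        memo = {}
    if x <= 0:
        return 0.0
    if t == cfg.T:
        if x < cfg.x_crit:
            return 0.0
        if cfg.variant in ("model3a", "model3b"):
            rho = cfg.omega_z0 + (cfg.omega_zA - cfg.omega_z0) * a / cfg.A
        else:
            rho = 1.0
        return (x / cfg.X) ** cfg.q * rho
    key = (x, a, t)
    if key in memo:
        return memo[key]
    best = 0.0
    for action in range(3):
        c = (cfg.c_f, cfg.c_p, cfg.c_r)[action]
        s = (cfg.s_f, cfg.s_p, 0.0)[action]
        if action == 0:
            m = cfg.m_f0 + (cfg.m_fA - cfg.m_f0) * a / cfg.A
            yz = cfg.y_z0 + (cfg.y_zA - cfg.y_z0) * a / cfg.A
            food = [(cfg.y_e, yz), (0, 1.0 - yz)]
        elif action == 1:
            m, food = cfg.m_p, [(0, 1.0)]
        else:
            m, food = cfg.m_r, [(0, 1.0)]
        prov = [(cfg.w_e, cfg.w_z), (0, 1.0 - cfg.w_z)] if t < cfg.tau else [(0, 1.0)]
        ev = 0.0
        for g_f, p_f in food:
            for g_w, p_w in prov:
                xn = min(x - c + g_f + g_w, cfg.X)
                for d_a, p_a in ((1, s), (0, 1.0 - s)):
                    if p_a == 0.0:
                        continue
                    ev += p_f * p_w * p_a * oracle_value(cfg, xn, min(a + d_a, cfg.A), t + 1, memo)
        best = max(best, (1.0 - m) * ev)
    memo[key] = best
    return best


@pytest.fixture(scope="session")
def solved_full():
    """Cache of fully solved default variants: variant -> (cfg, value, policy)."""
    cache: dict[str, tuple] = {}

    def get(variant: str):
        if variant not in cache:
            cfg = ps.ModelConfig.for_variant(variant)
            value, policy = ps.backward_induce(cfg)
            cache[variant] = (cfg, value, policy)
        return cache[variant]

    return get


@pytest.fixture(scope="session")
def trajectories_from_100(solved_full):
    """Forward propagation of each default variant from x=100, a=0."""
    cache: dict[str, ps.CohortTrajectory] = {}

    def get(variant: str):
        if variant not in cache:
            cfg, value, policy = solved_full(variant)
            cache[variant] = ps.forward_propagate(value, policy, cfg, 100, 0)
        return cache[variant]

    return get


@pytest.fixture(scope="session")
def solved_mini():
    """Cache of solved miniature variants."""
    cache: dict[str, tuple] = {}

    def get(variant: str):
        if variant not in cache:
            cfg = mini_config(variant)
            value, policy = ps.backward_induce(cfg)
            cache[variant] = (cfg, value, policy)
        return cache[variant]

    return get
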