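"""Exact finite-horizon backward induction over the (energy, ability) grid.

Solves the Bellman recursion

    U*(x, a, T) = terminal_reward(x, a)
    U*(x, a, t) = max_action  E[ U*(x', a', t+1) ]      (death contributes 0)

for every state, and records the maximising activity Psi(x, a, t).  States
whose optimal value is exactly zero (the horizon cannot be reached with a
payoff) are marked ``none``: no behaviour is optimal there.

The induction is vectorised over the whole (x, a) plane: each activity's
expectation is a weighted sum over at most four energy outcomes (foraging
yield x provisioning) of an ability-mixed value slice, multiplied by the
activity's survival probability.  A scalar single-state expectation
(:func:`action_value`) built directly on the enumerated transition kernel is
kept as the reference path for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    ACTIONS,
    ACTION_NAMES,
    CHOICE_NAMES,
    FORAGE,
    NONE,
    PLAY,
    REST,
    ModelConfig,
    State,
    terminal_reward,
    transition_distribution,
)

__all__ = ["ValueFunction", "Policy", "action_value", "backward_induce", "policy_slice"]

# Consistency tolerance for comparing action values against U* in checks;
# tie detection itself uses exact equality (see backward_induce), with ties
# resolving to the lowest-mortality activity (rest, then play, then forage).
TIE_TOL = 1e-12


@dataclass
class ValueFunction:
    """Optimal value U*(x, a, t) on the full grid, shape (T+1, X+1, A+1)."""

    values: np.ndarray
    config: ModelConfig

    def at(self, x: int, a: int, t: int) -> float:
        return float(self.values[t, x, a])


@dataclass
class Policy:
    """Optimal choice Psi(x, a, t), shape (T, X+1, A+1).

    ``choices`` holds int8 codes ``FORAGE, PLAY, REST, NONE``; ``NONE``
    marks zero-value states (and the dead level x = 0, which never acts).

    The optimum is not always unique: wherever reordering play and forage
    steps cannot change the expected payoff the two action values are
    exactly equal, and such ties cover large state regions in the
    terminal-reward variants.  ``optimal_set`` therefore records the full
    set of exactly optimal actions per state as a bitmask (bit ``action``
    set iff that action attains the maximum; 0 for zero-value states).
    ``choices`` is the deterministic representative obtained by breaking
    ties toward the lowest-mortality activity (rest, then play, then
    forage); the cohort models consume ``optimal_set``.
    """

    choices: np.ndarray
    config: ModelConfig
    optimal_set: np.ndarray | None = None

    def at(self, x: int, a: int, t: int) -> str:
        return CHOICE_NAMES[self.choices[t, x, a]]

    def n_optimal(self) -> np.ndarray:
        """Number of tied optimal actions per state (0 for none-states)."""
        m = self.optimal_set
        return ((m & 1) + ((m >> 1) & 1) + ((m >> 2) & 1)).astype(np.int8)


def action_value(state: State, action: int, next_values: np.ndarray, config: ModelConfig) -> float:
    """Expected next-step value of one activity in one state.

    ``next_values`` is the (X+1, A+1) value slice at ``t + 1``; death
    branches contribute zero.
    """
    dist = transition_distribution(state, action, config)
    return float(sum(p * next_values[xn, an] for xn, an, p in dist.branches))


def _energy_branches(config: ModelConfig, action: int, provisioned: bool):
    """Energy-gain outcomes as (probability, gain) pairs.

    The probability is a scalar or, for foraging success (ability-dependent
    in model 2), an array over the ability axis.
    """
    A = config.A
    if action == FORAGE:
        yz = config.forage_success(np.arange(A + 1))
        forage = [(yz, config.y_e), (1.0 - yz, 0)]
    else:
        forage = [(1.0, 0)]
    if provisioned:
        prov = [(config.w_z, config.w_e), (1.0 - config.w_z, 0)]
    else:
        prov = [(1.0, 0)]
    out = []
    for p_f, g_f in forage:
        for p_w, g_w in prov:
            out.append((p_f * p_w, g_f + g_w))
    return out


def _action_value_grid(V_next: np.ndarray, action: int, provisioned: bool, config: ModelConfig) -> np.ndarray:
    """Vectorised expectation of ``V_next`` for one activity over all (x, a)."""
    X, A = config.X, config.A
    a_up = np.minimum(np.arange(A + 1) + 1, A)
    s = config.skill_prob(action)
    # Ability mixing first: increments are independent of the energy outcome.
    W = (1.0 - s) * V_next + s * V_next[:, a_up] if s else V_next
    x_idx = np.arange(X + 1)
    c = config.cost(action)
    EV = np.zeros_like(V_next)
    for p, gain in _energy_branches(config, action, provisioned):
        nxt = np.clip(x_idx - c + gain, 0, X)  # row 0 is the dead level, value 0
        EV += p * W[nxt, :]
    m = config.mortality(action, np.arange(A + 1))
    return (1.0 - m) * EV


def backward_induce(config: ModelConfig) -> tuple[ValueFunction, Policy]:
    """Solve the model exactly by backward induction.

    Returns the full value function (t = 0..T) and the policy (t = 0..T-1).
    Ties between activities within ``TIE_TOL`` resolve to rest, then play,
    then forage; zero-value states get ``NONE``.
    """
    X, A, T = config.X, config.A, config.T
    values = np.zeros((T + 1, X + 1, A + 1))
    choices = np.full((T, X + 1, A + 1), NONE, dtype=np.int8)
    optimal_set = np.zeros((T, X + 1, A + 1), dtype=np.uint8)

    xs = np.arange(X + 1)[:, None]
    as_ = np.arange(A + 1)[None, :]
    VT = terminal_reward(xs, as_, config)
    VT[0, :] = 0.0  # x = 0 is dead regardless of the reward formula
    values[T] = VT

    for t in range(T - 1, -1, -1):
        provisioned = t < config.tau
        V_next = values[t + 1]
        Q = [_action_value_grid(V_next, action, provisioned, config) for action in ACTIONS]
        best = np.maximum(np.maximum(Q[FORAGE], Q[PLAY]), Q[REST])
        pol = np.full((X + 1, A + 1), NONE, dtype=np.int8)
        mask = np.zeros((X + 1, A + 1), dtype=np.uint8)
        eligible = best > 0.0
        # An action is a co-optimum iff its value equals the maximum exactly
        # (ties in these models arise from exact order-indifference, not
        # rounding).  The representative choice assigns in increasing-
        # preference order so the preferred co-optimum wins.
        for action in (FORAGE, PLAY, REST):
            tied = eligible & (Q[action] == best)
            pol[tied] = action
            mask |= tied.astype(np.uint8) << action
        best = best.copy()
        best[0, :] = 0.0
        pol[0, :] = NONE
        mask[0, :] = 0
        values[t] = best
        choices[t] = pol
        optimal_set[t] = mask

    return ValueFunction(values, config), Policy(choices, config, optimal_set)


def policy_slice(policy: Policy, fixed_a: int) -> pd.DataFrame:
    """Exhaustive (t, x) choice table at one ability level (the policy-map panel).

    Rows cover t = 0..T-1 and live reserves x = 1..X.
    """
    config = policy.config
    if not (0 <= fixed_a <= config.A):
        raise ValueError(f"ability {fixed_a} outside 0..{config.A}")
    T, X = config.T, config.X
    grid = policy.choices[:, 1:, fixed_a]  # (T, X)
    t_col = np.repeat(np.arange(T), X)
    x_col = np.tile(np.arange(1, X + 1), T)
    names = np.array(CHOICE_NAMES)
    return pd.DataFrame({"t": t_col, "x": x_col, "choice": names[grid.ravel()]})
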