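"""Deterministic forward propagation of a cohort under the optimal policy.

Starting from a unit point mass at ``(x_start, a_start)`` at ``t = 0``, the
probability mass over live states is pushed through the same one-step
kernel the solver uses, following the solved choice function.  Mass landing
in zero-value states (``Psi = none``) is absorbed into a "no payoff" class
before acting; predation and starvation are tracked as separate absorbing
classes.  The trajectory yields the activity time-courses, marginal state
densities, and lifetime activity budgets that summarise the predicted
ontogeny of play.

Where several actions are exactly co-optimal (a pervasive degeneracy in the
terminal-reward variants, where the order of play and forage steps is
value-irrelevant) the mass in that state is split equally among the tied
optima: an indifferent population realises every optimal schedule, and any
single deterministic tie order would instead make the whole cohort switch
activity in lockstep.  The expected payoff is unaffected.

Two normalisations are exposed deliberately: per-timestep activity
proportions are fractions of the *initial* cohort (the stacked-area figure
convention, where the no-payoff line completes each timestep to 1), while
the lifetime budget divides each activity's summed mass by the total acting
mass (the convention behind the 5%-of-lifetime play criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    ACTIONS,
    ACTION_NAMES,
    FORAGE,
    NONE,
    PLAY,
    REST,
    ModelConfig,
    terminal_reward,
)
from .dp_solver import Policy, ValueFunction, _energy_branches

__all__ = [
    "CohortTrajectory",
    "forward_propagate",
    "activity_timecourse",
    "lifetime_budget",
    "state_density",
    "headline_stats",
    "MASS_FLOOR",
]

# Activity mass below this fraction of the initial cohort counts as absent
# when detecting onsets and exclusive-activity phases.  The forward model
# always carries vanishing tails (1e-9..1e-4) of off-activity mass from
# improbable reserve histories, so exclusivity is a statement about
# population-visible proportions: the floor is one individual per thousand,
# below what a stacked proportion curve can resolve.
MASS_FLOOR = 1e-3


@dataclass
class CohortTrajectory:
    """Propagated cohort: per-timestep masses, absorptions, and marginals.

    ``activity_mass[t, action]`` is the mass performing each activity at
    decision step ``t`` (fraction of the initial cohort).  ``active_mass``,
    the cumulative absorption arrays and the state marginals are snapshots
    taken after the no-payoff absorption at each ``t`` (index ``T`` is the
    post-horizon state).  At every ``t``,
    ``active + dead_predation + dead_starvation + no_payoff = 1``.
    """

    config: ModelConfig
    x_start: int
    a_start: int
    activity_mass: np.ndarray        # (T, 3)
    active_mass: np.ndarray          # (T+1,)
    dead_predation_cum: np.ndarray   # (T+1,)
    dead_starvation_cum: np.ndarray  # (T+1,)
    no_payoff_cum: np.ndarray        # (T+1,)
    x_marginal: np.ndarray           # (T+1, X+1)
    a_marginal: np.ndarray           # (T+1, A+1)
    mean_x: np.ndarray               # (T+1,)
    mean_a: np.ndarray               # (T+1,)
    expected_terminal_payoff: float = 0.0

    @property
    def absorbed_cum(self) -> np.ndarray:
        """Total no-payoff mass in the figure sense: dead plus unreachable."""
        return self.dead_predation_cum + self.dead_starvation_cum + self.no_payoff_cum


def forward_propagate(value: ValueFunction, policy: Policy, config: ModelConfig,
                      x_start: int, a_start: int) -> CohortTrajectory:
    """Push a unit point mass through the solved policy for t = 0..T-1."""
    X, A, T = config.X, config.A, config.T
    if not (1 <= x_start <= X):
        raise ValueError(f"x_start must be a live reserve level in 1..{X}, got {x_start}")
    if not (0 <= a_start <= A):
        raise ValueError(f"a_start outside 0..{A}")

    mass = np.zeros((X + 1, A + 1))
    mass[x_start, a_start] = 1.0

    activity_mass = np.zeros((T, 3))
    active = np.zeros(T + 1)
    cum_pred = np.zeros(T + 1)
    cum_starve = np.zeros(T + 1)
    cum_nopay = np.zeros(T + 1)
    x_marg = np.zeros((T + 1, X + 1))
    a_marg = np.zeros((T + 1, A + 1))

    x_idx = np.arange(X + 1)
    a_idx = np.arange(A + 1)
    dead_pred = dead_starve = no_payoff = 0.0

    if policy.optimal_set is None:
        # Degrade gracefully to the single representative choice.
        opt = np.zeros_like(policy.choices, dtype=np.uint8)
        for action in ACTIONS:
            opt |= (policy.choices == action).astype(np.uint8) << action
    else:
        opt = policy.optimal_set

    for t in range(T + 1):
        if t < T:
            mask_t = opt[t]
            none_mask = mask_t == 0
            no_payoff += mass[none_mask].sum()
            mass = np.where(none_mask, 0.0, mass)
        active[t] = mass.sum()
        cum_pred[t], cum_starve[t], cum_nopay[t] = dead_pred, dead_starve, no_payoff
        x_marg[t] = mass.sum(axis=1)
        a_marg[t] = mass.sum(axis=0)
        if t == T:
            break

        new_mass = np.zeros_like(mass)
        provisioned = t < config.tau
        n_opt = ((mask_t & 1) + ((mask_t >> 1) & 1) + ((mask_t >> 2) & 1)).astype(float)
        n_opt[n_opt == 0] = 1.0
        for action in ACTIONS:
            sel = mass * (((mask_t >> action) & 1) / n_opt)
            tot = sel.sum()
            activity_mass[t, action] = tot
            if tot == 0.0:
                continue
            m = config.mortality(action, a_idx)
            dead_pred += float((sel * m).sum())
            surv = sel * (1.0 - m)
            s = config.skill_prob(action)
            c = config.cost(action)
            for p, gain in _energy_branches(config, action, provisioned):
                # Branch probabilities (e.g. foraging success) are evaluated
                # at the pre-step ability, so weight before the ability shift.
                C = surv * p
                if s:
                    B = (1.0 - s) * C
                    B[:, 1:] += s * C[:, :-1]
                    B[:, -1] += s * C[:, -1]  # ability caps at A
                    C = B
                tgt = x_idx - c + gain
                starving = tgt <= 0
                if starving.any():
                    dead_starve += float(C[starving].sum())
                rows = np.nonzero(~starving)[0]
                np.add.at(new_mass, np.clip(tgt[rows], 1, X), C[rows])
        mass = new_mass

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = np.where(active > 0, x_marg @ x_idx / np.where(active > 0, active, 1.0), np.nan)
        mean_a = np.where(active > 0, a_marg @ a_idx / np.where(active > 0, active, 1.0), np.nan)

    reward_T = np.asarray(terminal_reward(x_idx[:, None], a_idx[None, :], config))
    reward_T[0, :] = 0.0
    payoff = float((mass * reward_T).sum())

    return CohortTrajectory(
        config=config, x_start=x_start, a_start=a_start,
        activity_mass=activity_mass, active_mass=active,
        dead_predation_cum=cum_pred, dead_starvation_cum=cum_starve,
        no_payoff_cum=cum_nopay, x_marginal=x_marg, a_marginal=a_marg,
        mean_x=mean_x, mean_a=mean_a, expected_terminal_payoff=payoff,
    )


def activity_timecourse(trajectory: CohortTrajectory) -> pd.DataFrame:
    """Per-timestep activity proportions as fractions of the initial cohort.

    Columns: ``t, p_forage, p_play, p_rest, p_no_payoff_cum`` for
    t = 0..T-1; the no-payoff column pools death by predation, death by
    starvation, and absorbed unreachable-payoff mass, so each row sums to 1.
    """
    T = trajectory.config.T
    df = pd.DataFrame({
        "t": np.arange(T),
        "p_forage": trajectory.activity_mass[:, FORAGE],
        "p_play": trajectory.activity_mass[:, PLAY],
        "p_rest": trajectory.activity_mass[:, REST],
        "p_no_payoff_cum": trajectory.absorbed_cum[:T],
    })
    return df


def lifetime_budget(trajectory: CohortTrajectory) -> tuple[float, float, float]:
    """Lifetime activity shares: each activity's mass over total acting mass.

    Returns ``(share_forage, share_play, share_rest)`` summing to 1.  A
    cohort absorbed immediately (zero acting mass) is degenerate: a warning
    is raised and the shares are NaN.
    """
    totals = trajectory.activity_mass.sum(axis=0)
    grand = totals.sum()
    if grand <= 0.0:
        warnings.warn("cohort absorbed before acting: lifetime budget undefined",
                      stacklevel=2)
        return (float("nan"),) * 3
    shares = totals / grand
    return float(shares[FORAGE]), float(shares[PLAY]), float(shares[REST])


def state_density(trajectory: CohortTrajectory, axis: str) -> pd.DataFrame:
    """Marginal state density over energy or ability per timestep.

    Columns: ``t, level, mass, ge10pct`` where the flag marks levels holding
    at least 10% of the initial cohort (the bright band of the density maps).
    """
    if axis == "energy":
        marg = trajectory.x_marginal
    elif axis == "ability":
        marg = trajectory.a_marginal
    else:
        raise ValueError(f"axis must be 'energy' or 'ability', got {axis!r}")
    T1, L = marg.shape
    return pd.DataFrame({
        "t": np.repeat(np.arange(T1), L),
        "level": np.tile(np.arange(L), T1),
        "mass": marg.ravel(),
        "ge10pct": (marg.ravel() >= 0.1).astype(int),
    })


def headline_stats(trajectory: CohortTrajectory) -> dict:
    """Summary statistics of the predicted ontogeny of play.

    * ``first_play_t`` — first timestep with play mass above the floor (-1 if none).
    * ``play_only_prefix`` — length of the initial run where play is the only
      activity above the floor.
    * ``rest_only_suffix`` — length of the final run (ending at T-1) where
      rest is the only activity above the floor.
    * ``majority_max_ability_t`` — first timestep where more than half of the
      active mass sits at the ability cap ``a = A`` (-1 if never).
    * lifetime shares and the expected terminal payoff.
    """
    T = trajectory.config.T
    am = trajectory.activity_mass
    play_on = am[:, PLAY] > MASS_FLOOR
    first_play = int(np.argmax(play_on)) if play_on.any() else -1

    acting = am.sum(axis=1) > MASS_FLOOR
    play_only = acting & (am[:, FORAGE] <= MASS_FLOOR) & (am[:, REST] <= MASS_FLOOR)
    prefix = 0
    while prefix < T and play_only[prefix]:
        prefix += 1
    rest_only = acting & (am[:, FORAGE] <= MASS_FLOOR) & (am[:, PLAY] <= MASS_FLOOR)
    suffix = 0
    while suffix < T and rest_only[T - 1 - suffix]:
        suffix += 1

    A = trajectory.config.A
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_max = np.where(trajectory.active_mass > 0,
                            trajectory.a_marginal[:, A]
                            / np.where(trajectory.active_mass > 0, trajectory.active_mass, 1.0),
                            0.0)
    over = frac_max > 0.5
    majority_t = int(np.argmax(over)) if over.any() else -1

    share_f, share_p, share_r = lifetime_budget(trajectory)
    return {
        "first_play_t": first_play,
        "play_only_prefix": prefix,
        "rest_only_suffix": suffix,
        "majority_max_ability_t": majority_t,
        "share_forage": share_f,
        "share_play": share_p,
        "share_rest": share_r,
        "expected_terminal_payoff": trajectory.expected_terminal_payoff,
    }
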