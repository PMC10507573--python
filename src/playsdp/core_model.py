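"""Shared state-dependent model of juvenile activity choice.

An individual tracked over discrete time ``t = 0..T`` carries two integer
state variables: energy reserves ``x`` (0..X, with ``x = 0`` the absorbing
starvation level) and an acquired ability ``a`` (0..A).  At every decision
step it allocates its free time to one of three activities — foraging,
playing, or resting — each with its own energy cost, predation risk, and
probability of improving ability.  Parental provisioning supplies extra
energy while ``t < tau``.  At the horizon ``T`` the individual is paid off
only if its reserves reach a critical level ``x_crit`` (interpreted as the
energetic requirement for reproduction at sexual maturity).

Four variants differ only in what the ability does:

* ``model1`` — ability lowers the predation risk of foraging, linearly from
  ``m_f0`` at ``a = 0`` down to ``m_fA`` (= the play risk) at ``a = A``.
* ``model2`` — ability raises the probability of foraging success, linearly
  from ``y_z0`` to ``y_zA``.
* ``model3a`` / ``model3b`` — ability multiplies the terminal payoff by a
  reproduction probability rising linearly from ``omega_z0`` to ``omega_zA``;
  in ``model3a`` foraging gives no practice (``s_f = 0``), in ``model3b`` it
  gives better practice than play (``s_f > s_p``).

This module owns the parameter container, the ability-dependent rate
functions, the terminal reward, and the one-step stochastic transition
kernel that the solver, the forward cohort model, and the Monte-Carlo
simulator all share.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "FORAGE",
    "PLAY",
    "REST",
    "NONE",
    "ACTIONS",
    "ACTION_NAMES",
    "CHOICE_NAMES",
    "VARIANTS",
    "ConfigWarning",
    "ModelConfig",
    "State",
    "TransitionDistribution",
    "linear_ability_map",
    "terminal_reward",
    "transition_distribution",
]

# Activity codes used in every policy / trajectory array.
FORAGE, PLAY, REST, NONE = 0, 1, 2, 3
ACTIONS = (FORAGE, PLAY, REST)
ACTION_NAMES = ("forage", "play", "rest")
CHOICE_NAMES = ("forage", "play", "rest", "none")

VARIANTS = ("model1", "model2", "model3a", "model3b")

# Defaults shared by every variant; variant-specific entries below override.
_BASE_DEFAULTS = dict(
    X=300,
    A=100,
    T=200,
    tau=50,
    w_e=3,
    w_z=0.7,
    y_e=5,
    y_z0=0.7,
    y_zA=0.7,
    c_f=2,
    c_p=3,
    c_r=1,
    m_f0=0.002,
    m_fA=0.002,
    m_p=0.0002,
    m_r=0.0001,
    s_f=0.8,
    s_p=0.5,
    x_crit=150,
    q=0.0,
    omega_z0=0.1,
    omega_zA=0.9,
)

_INT_FIELDS = frozenset({"X", "A", "T", "tau", "w_e", "y_e", "c_f", "c_p", "c_r", "x_crit"})

_PROB_FIELDS = (
    "w_z", "y_z0", "y_zA", "m_f0", "m_fA", "m_p", "m_r",
    "s_f", "s_p", "omega_z0", "omega_zA",
)


class ConfigWarning(UserWarning):
    """Soft violation of an advisory parameter ordering (e.g. c_f > c_p)."""


class State(NamedTuple):
    """A single point of the (energy, ability, time) grid."""

    x: int
    a: int
    t: int


@dataclass(frozen=True)
class ModelConfig:
    """All scalar parameters of the model plus the variant selector.

    Constructed directly, or via :meth:`for_variant` which fills the
    variant-specific defaults (ability-coupled endpoints) before applying
    user overrides.
    """

    variant: str = "model1"
    X: int = 300
    A: int = 100
    T: int = 200
    tau: int = 50
    w_e: int = 3
    w_z: float = 0.7
    y_e: int = 5
    y_z0: float = 0.7
    y_zA: float = 0.7
    c_f: int = 2
    c_p: int = 3
    c_r: int = 1
    m_f0: float = 0.002
    m_fA: float = 0.002
    m_p: float = 0.0002
    m_r: float = 0.0001
    s_f: float = 0.8
    s_p: float = 0.5
    x_crit: int = 150
    q: float = 0.0
    omega_z0: float = 0.1
    omega_zA: float = 0.9

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in _INT_FIELDS:
            v = getattr(self, name)
            if v != int(v):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.X <= 0 or self.A < 0 or self.T <= 0:
            raise ValueError("X and T must be positive, A nonnegative")
        if not (0 < self.x_crit <= self.X):
            raise ValueError(f"x_crit must satisfy 0 < x_crit <= X, got {self.x_crit} (X={self.X})")
        if not (0 < self.tau <= self.T):
            raise ValueError(f"tau must satisfy 0 < tau <= T, got {self.tau} (T={self.T})")
        for name in _PROB_FIELDS:
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
            object.__setattr__(self, name, v)
        if self.q < 0:
            raise ValueError(f"q must be nonnegative, got {self.q}")
        if self.w_e < 0 or self.y_e < 0:
            raise ValueError("energy gains w_e, y_e must be nonnegative")
        # c_r may be negative (rest with net energy gain); costs otherwise free.
        if self.c_f > self.c_p:
            warnings.warn(
                f"c_f={self.c_f} exceeds c_p={self.c_p}: play is usually at least "
                "as costly as foraging", ConfigWarning, stacklevel=2)
        if self.m_r > self.m_p:
            warnings.warn(
                f"m_r={self.m_r} exceeds m_p={self.m_p}: rest is usually the "
                "safest activity", ConfigWarning, stacklevel=2)

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "ModelConfig":
        """Build a config with the variant's published defaults, then overrides.

        Variant rules:

        * ``model1``: ``m_f0 = 0.005`` and ``m_fA`` coupled to ``m_p`` (the
          coupling tracks an overridden ``m_p`` unless ``m_fA`` is given
          explicitly).
        * ``model2``: ``y_z0 = 0.1``, ``y_zA = 0.9``.
        * ``model3a``: ``s_f = 0`` (foraging offers no practice).
        * ``model3b``: base defaults (``s_f = 0.8 > s_p``).
        """
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        params = dict(_BASE_DEFAULTS)
        if variant == "model1":
            params["m_f0"] = 0.005
            params["m_fA"] = overrides.get("m_p", params["m_p"])
        elif variant == "model2":
            params["y_z0"] = 0.1
            params["y_zA"] = 0.9
        elif variant == "model3a":
            params["s_f"] = 0.0
        unknown = set(overrides) - set(params)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        params.update(overrides)
        return cls(variant=variant, **params)

    def with_param(self, name: str, value) -> "ModelConfig":
        """Return a copy with one parameter replaced, keeping variant couplings.

        Accepts the alias names ``m_f`` (sets both endpoints of the foraging
        mortality) and ``y_z`` (both endpoints of foraging success).  In
        ``model1``, changing ``m_p`` also moves the coupled upper mortality
        endpoint ``m_fA`` when the coupling ``m_fA = m_p`` is intact.
        """
        updates: dict = {}
        if name == "m_f":
            updates = {"m_f0": value, "m_fA": value}
        elif name == "y_z":
            updates = {"y_z0": value, "y_zA": value}
        elif name == "m_p" and self.variant == "model1" and self.m_fA == self.m_p:
            updates = {"m_p": value, "m_fA": value}
        elif name in {f.name for f in dataclasses.fields(self)} - {"variant"}:
            updates = {name: value}
        else:
            raise ValueError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **updates)

    # ------------------------------------------------------------------
    # derived rate functions
    # ------------------------------------------------------------------
    def forage_mortality(self, a):
        """Predation risk per foraging timestep at ability ``a`` (scalar or array)."""
        return linear_ability_map(a, self.m_f0, self.m_fA, self.A)

    def forage_success(self, a):
        """Probability that a foraging timestep yields ``y_e`` at ability ``a``."""
        return linear_ability_map(a, self.y_z0, self.y_zA, self.A)

    def reproduction_prob(self, a):
        """Terminal reproduction probability; identically 1 outside models 3a/3b."""
        if self.variant in ("model3a", "model3b"):
            return linear_ability_map(a, self.omega_z0, self.omega_zA, self.A)
        return np.ones_like(np.asarray(a, dtype=float)) if np.ndim(a) else 1.0

    def cost(self, action: int) -> int:
        return (self.c_f, self.c_p, self.c_r)[action]

    def skill_prob(self, action: int) -> float:
        """Probability that the activity increments ability by one (rest: 0)."""
        return (self.s_f, self.s_p, 0.0)[action]

    def mortality(self, action: int, a):
        """Predation risk of the activity at ability ``a``."""
        if action == FORAGE:
            return self.forage_mortality(a)
        return self.m_p if action == PLAY else self.m_r

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def linear_ability_map(a, v0: float, vA: float, A: int):
    """Linear interpolation of a rate between its ``a = 0`` and ``a = A`` endpoints.

    Works elementwise on arrays.  Raises if any ability is outside ``0..A``.
    """
    arr = np.asarray(a)
    if np.any(arr < 0) or np.any(arr > A):
        raise ValueError(f"ability {a!r} outside 0..{A}")
    f = arr / A if A > 0 else np.zeros_like(arr, dtype=float)
    out = v0 * (1.0 - f) + vA * f  # convex form: exact at both endpoints
    return float(out) if np.ndim(a) == 0 else out


def terminal_reward(x, a, config: ModelConfig):
    """Payoff at the horizon ``T``.

    Zero below the critical reserve level ``x_crit``; otherwise
    ``(x/X)**q`` times the reproduction probability (ability-dependent in
    models 3a/3b, 1 otherwise).  The default ``q = 0`` collapses the reserve
    factor to the published binary payoff.
    """
    x_arr = np.asarray(x)
    a_arr = np.asarray(a)
    if np.any(x_arr < 0) or np.any(x_arr > config.X):
        raise ValueError(f"reserves {x!r} outside 0..{config.X}")
    g = np.where(x_arr >= config.x_crit, (x_arr / config.X) ** config.q, 0.0)
    out = g * config.reproduction_prob(a_arr)
    return float(out) if np.ndim(x) == 0 and np.ndim(a) == 0 else out


@dataclass
class TransitionDistribution:
    """One-step outcome distribution of a live state under one activity.

    ``branches`` lists the surviving, non-starving outcomes as
    ``(x_next, a_next, probability)``; ``death_probability`` pools predation
    and starvation (both yield value 0).
    """

    branches: list = field(default_factory=list)
    death_probability: float = 0.0

    def total(self) -> float:
        return self.death_probability + sum(p for _, _, p in self.branches)


def transition_distribution(state: State, action: int, config: ModelConfig) -> TransitionDistribution:
    """Enumerate the joint outcome tree of one decision.

    Events within a timestep: predation (probability ``m`` of the activity)
    removes the individual; survivors pay the activity cost, collect the
    stochastic foraging yield (foraging only) and parental provision
    (``t < tau`` only), are capped at ``X``, and starve if reserves fall to
    zero or below.  Ability increments by one (capped at ``A``) with the
    activity's practice probability, independently of the energy outcomes.
    Provisioning received in the same step can rescue an individual from
    starvation.
    """
    x, a, t = state
    if not (0 <= a <= config.A and 0 <= x <= config.X and 0 <= t <= config.T):
        raise ValueError(f"state {state} outside the grid")
    if x == 0:
        raise ValueError("transition requested for a dead (x = 0) state")
    if t >= config.T:
        raise ValueError(f"no decision at or beyond the horizon t = {config.T}")
    if action not in ACTIONS:
        raise ValueError(f"invalid action code {action}")

    m = float(config.mortality(action, a))
    s = config.skill_prob(action)
    c = config.cost(action)

    forage_branches = [(0, 1.0)]
    if action == FORAGE:
        yz = float(config.forage_success(a))
        forage_branches = [(config.y_e, yz), (0, 1.0 - yz)]
    prov_branches = [(0, 1.0)]
    if t < config.tau:
        prov_branches = [(config.w_e, config.w_z), (0, 1.0 - config.w_z)]
    abil_branches = [(1, s), (0, 1.0 - s)]

    merged: dict[tuple[int, int], float] = {}
    death = m
    survive = 1.0 - m
    for g_f, p_f in forage_branches:
        for g_w, p_w in prov_branches:
            x_next = min(x - c + g_f + g_w, config.X)
            for d_a, p_a in abil_branches:
                p = survive * p_f * p_w * p_a
                if p == 0.0:
                    continue
                if x_next <= 0:
                    death += p
                else:
                    key = (x_next, min(a + d_a, config.A))
                    merged[key] = merged.get(key, 0.0) + p
    branches = [(xn, an, p) for (xn, an), p in sorted(merged.items())]
    return TransitionDistribution(branches=branches, death_probability=death)
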