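"""One-at-a-time (OAT) sensitivity sweeps over the model parameters.

For each value on a parameter grid the model is re-solved from scratch, the
cohort is propagated forward, and the lifetime activity budget is recorded.
The headline summary is the range of parameter values over which the
lifetime play share meets a threshold (5% by default) while every other
parameter stays at the variant's defaults.

The published grids behind the printed ranges are not available, so the
default grids here take evenly spaced points across each parameter's
sensitivity span; reported qualifying ranges are therefore grid-resolution
approximations and any grid can be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import FORAGE, PLAY, REST, ModelConfig
from .dp_solver import backward_induce
from .forward_model import forward_propagate, lifetime_budget

__all__ = ["SweepResult", "oat_sweep", "qualifying_range", "default_grid", "SWEEP_SPANS"]

PLAY_THRESHOLD = 0.05

# Sensitivity spans per parameter: (low, high, integer-valued).  Spans follow
# the ranges explored for each parameter in the published sensitivity
# analysis where stated; grids are overridable everywhere.
SWEEP_SPANS: dict[str, tuple[float, float, bool]] = {
    "X": (150, 600, True),
    "A": (10, 250, True),
    "T": (50, 350, True),
    "tau": (1, 100, True),
    "w_e": (0, 10, True),
    "w_z": (0.0, 1.0, False),
    "y_e": (1, 10, True),
    "y_z": (0.0, 1.0, False),
    "y_z0": (0.0, 1.0, False),
    "c_f": (1, 5, True),
    "c_p": (1, 14, True),
    "c_r": (-1, 3, True),
    "m_f": (0.0, 0.06, False),
    "m_f0": (0.0, 0.06, False),
    "m_p": (0.0, 0.06, False),
    "m_r": (0.0, 0.06, False),
    "s_f": (0.0, 1.0, False),
    "s_p": (0.0, 1.0, False),
    "x_crit": (1, 265, True),
    "q": (0.0, 2.0, False),
    "omega_z0": (0.0, 0.9, False),
}


def default_grid(parameter: str, n_points: int = 16) -> np.ndarray:
    """Evenly spaced sweep grid across the parameter's sensitivity span."""
    if parameter not in SWEEP_SPANS:
        raise ValueError(f"no default sweep span for parameter {parameter!r}")
    lo, hi, is_int = SWEEP_SPANS[parameter]
    grid = np.linspace(lo, hi, n_points)
    if is_int:
        grid = np.unique(np.rint(grid).astype(int))
    return grid


@dataclass
class SweepResult:
    """Per-value lifetime budgets of one OAT sweep plus the qualifying range."""

    parameter: str
    values: np.ndarray
    shares: np.ndarray          # (k, 3): forage, play, rest
    threshold: float = PLAY_THRESHOLD
    x_start: int = 50
    a_start: int = 0
    intervals: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "value": self.values,
            "share_forage": self.shares[:, FORAGE],
            "share_play": self.shares[:, PLAY],
            "share_rest": self.shares[:, REST],
            "qualifies": (self.shares[:, PLAY] >= self.threshold).astype(int),
        })


def oat_sweep(config: ModelConfig, parameter: str, grid=None,
              x_start: int = 50, a_start: int = 0,
              threshold: float = PLAY_THRESHOLD) -> SweepResult:
    """Sweep one parameter across a grid, re-solving the model at each value.

    All other parameters stay at ``config``'s values; variant couplings
    (e.g. the mortality endpoint tied to ``m_p`` in model 1) follow the
    swept value via :meth:`ModelConfig.with_param`.  Start state defaults to
    the sensitivity-analysis start (x = 50, a = 0).
    """
    if grid is None:
        grid = default_grid(parameter)
    values = np.asarray(grid)
    shares = np.zeros((len(values), 3))
    for i, v in enumerate(values):
        cfg = config.with_param(parameter, v.item() if hasattr(v, "item") else v)
        value_fn, policy = backward_induce(cfg)
        # Start states outgrown by a swept-down grid are degenerate, not errors.
        xs = min(x_start, cfg.X)
        as_ = min(a_start, cfg.A)
        traj = forward_propagate(value_fn, policy, cfg, xs, as_)
        shares[i] = lifetime_budget(traj)
    result = SweepResult(parameter=parameter, values=values, shares=shares,
                         threshold=threshold, x_start=x_start, a_start=a_start)
    result.intervals = qualifying_range(result, threshold)
    return result


def qualifying_range(sweep: SweepResult, threshold: float | None = None) -> list[tuple[float, float]]:
    """Maximal runs of consecutive grid values with play share >= threshold.

    Returns ``[(lo, hi), ...]`` closed intervals of grid values; disjoint
    runs (split ranges) yield multiple intervals, an empty list means the
    threshold is never met.  NaN shares (degenerate cohorts) never qualify.
    """
    if threshold is None:
        threshold = sweep.threshold
    ok = np.nan_to_num(sweep.shares[:, PLAY], nan=-1.0) >= threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(sweep.values[start]), float(sweep.values[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(sweep.values[start]), float(sweep.values[-1])))
    return intervals
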