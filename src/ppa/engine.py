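"""Process weights, activity classification and switching times.

The weight of process j in equation i at time t is its share of the total
absolute flux of that equation,

    W_ij(t) = |f_ij(x(t), p)| / sum_j |f_ij(x(t), p)|,

so that 0 <= W_ij <= 1 and each equation's weights sum to one wherever
the denominator is positive. A process is *active* at t when its weight
is at or above a threshold delta (0.1 by default), *inactive* otherwise,
and *always inactive* when its weight stays below delta over the whole
horizon. A *switching time* is an interior time at which a weight crosses
delta; crossings are located by linear interpolation between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ProcessModel, Trajectory

__all__ = [
    "AnalysisConfig",
    "WeightSeries",
    "ActivityProfile",
    "Switch",
    "SwitchingTimeSet",
    "compute_weights",
    "classify_activity",
    "activity_extrema",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Threshold and grid settings for an activity analysis."""

    delta: float = 0.1
    grid_step: float = 0.01
    horizon: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


@dataclass
class WeightSeries:
    """Relative process weights on a dense time grid."""

    grid: np.ndarray
    index: tuple[tuple[int, int], ...]  # (variable, position), 1-based
    weights: np.ndarray                 # shape (n_terms, n_times)
    denominators: np.ndarray            # shape (n_vars, n_times)
    variables: tuple[str, ...]

    def weight(self, i: int, j: int) -> np.ndarray:
        return self.weights[self.index.index((i, j))]

    def to_frame(self):
        """Long-format table ``time, variable, process, weight``."""
        import pandas as pd

        n_t = self.grid.size
        rows = []
        for k, (i, j) in enumerate(self.index):
            rows.append(pd.DataFrame({
                "time": self.grid,
                "variable": self.variables[i - 1],
                "process": f"f_{i},{j}",
                "weight": self.weights[k],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ActivityProfile:
    """Boolean activity of every process on the weight grid."""

    grid: np.ndarray
    index: tuple[tuple[int, int], ...]
    active: np.ndarray                  # bool, shape (n_terms, n_times)
    delta: float
    variables: tuple[str, ...]

    @property
    def always_inactive(self) -> frozenset[tuple[int, int]]:
        dead = ~self.active.any(axis=1)
        return frozenset(idx for idx, d in zip(self.index, dead) if d)

    @property
    def n_act(self) -> np.ndarray:
        """Number of simultaneously active processes at each grid time."""
        return self.active.sum(axis=0)

    def is_active(self, i: int, j: int) -> np.ndarray:
        return self.active[self.index.index((i, j))]


@dataclass(frozen=True, order=True)
class Switch:
    """A single threshold crossing of one process weight."""

    time: float
    index: tuple[int, int]
    direction: str  # "up" (inactive -> active) or "down"


@dataclass
class SwitchingTimeSet:
    """All interior threshold crossings, per variable and globally."""

    switches: tuple[Switch, ...]
    horizon: tuple[float, float]
    delta: float

    def per_variable(self, i: int) -> tuple[Switch, ...]:
        return tuple(s for s in self.switches if s.index[0] == i)

    def times(self, i: int | None = None) -> np.ndarray:
        """Sorted crossing times; the global set S when ``i`` is None."""
        sel = self.switches if i is None else self.per_variable(i)
        return np.sort(np.array([s.time for s in sel]))

    def __len__(self) -> int:
        return len(self.switches)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"variable": s.index[0], "process": f"f_{s.index[0]},{s.index[1]}",
              "time": s.time, "direction": s.direction}
             for s in sorted(self.switches)])


def compute_weights(model: ProcessModel, traj: Trajectory) -> WeightSeries:
    """Relative weight of every process along a trajectory.

    Where an equation's total absolute flux vanishes, all of its weights
    are set to 0 (no process contributes there).
    """
    grid = traj.grid
    fn = model._get_compiled("terms")
    n_terms = model.n_processes
    values = np.empty((n_terms, grid.size))

    # evaluate per forcing segment so the effective parameters are right
    from .model import _segment_bounds

    segs = _segment_bounds(model, float(grid[0]), float(grid[-1]))
    for a, b in zip(segs[:-1], segs[1:]):
        mask = (grid >= a) & (grid < b)
        mask |= np.isclose(grid, b) if b == segs[-1] else False
        if not mask.any():
            continue
        pvec = model.param_vector(dict(traj.params_used), t=0.5 * (a + b))
        cols = [traj.values[:, mask][k] for k in range(len(model.variables))]
        out = fn(grid[mask], *cols, *pvec)
        for k, arr in enumerate(out):
            values[k, mask] = np.broadcast_to(arr, (int(mask.sum()),))

    absval = np.abs(values)
    index = model.term_index
    var_of_term = np.array([i - 1 for i, _ in index])
    denom = np.zeros((len(model.variables), grid.size))
    np.add.at(denom, var_of_term, absval)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = absval / denom[var_of_term]
    weights[~np.isfinite(weights)] = 0.0
    return WeightSeries(grid=grid, index=index, weights=weights,
                        denominators=denom, variables=model.variables)


def classify_activity(
    weights: WeightSeries, cfg: AnalysisConfig
) -> tuple[ActivityProfile, SwitchingTimeSet]:
    """Threshold the weights and locate the interior crossings.

    A grid point is active when ``W >= delta``; each sign change of
    ``W - delta`` between adjacent grid points yields one switching time,
    placed by linear interpolation. Crossings falling exactly on the grid
    boundaries are discarded (only interior switches count).
    """
    delta = cfg.delta
    grid = weights.grid
    active = weights.weights >= delta
    profile = ActivityProfile(grid=grid, index=weights.index, active=active,
                              delta=delta, variables=weights.variables)

    t0, t1 = float(grid[0]), float(grid[-1])
    switches: list[Switch] = []
    for k, idx in enumerate(weights.index):
        w = weights.weights[k]
        a = active[k]
        flips = np.nonzero(a[:-1] != a[1:])[0]
        for q in flips:
            w0, w1 = w[q], w[q + 1]
            if w1 == w0:  # pragma: no cover - flips imply w0 != w1
                tc = grid[q]
            else:
                tc = grid[q] + (delta - w0) * (grid[q + 1] - grid[q]) / (w1 - w0)
            tc = float(np.clip(tc, grid[q], grid[q + 1]))
            if not (t0 < tc < t1):
                continue
            direction = "up" if a[q + 1] else "down"
            switches.append(Switch(time=tc, index=idx, direction=direction))
    return profile, SwitchingTimeSet(switches=tuple(sorted(switches)),
                                     horizon=(t0, t1), delta=delta)


def activity_extrema(profile: ActivityProfile) -> tuple[int, int]:
    """Minimum and maximum number of simultaneously active processes."""
    n = profile.n_act
    if n.size == 0:
        raise ValueError("empty activity profile")
    return int(n.min()), int(n.max())
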