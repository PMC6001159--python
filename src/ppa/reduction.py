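"""Model simplification: elimination, switching-time clustering,
sub-model schedules, reduction errors and an a-priori error bound.

Simplification replaces a process by zero wherever it is classified
inactive, leaving every kept term untouched. Processes that are inactive
only part of the time are handled by tiling the horizon into windows:
the detected switching times are grouped by exact one-dimensional
k-means, each cluster's mean becomes a *reduced switching time*, and all
processes whose crossings fall in a cluster are assumed to switch
together at its mean. Each window then has its own sub-model containing
only the processes active there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import ActivityProfile, SwitchingTimeSet
from .model import IntegrationError, ProcessModel, Trajectory, evaluate_outputs, simulate

__all__ = [
    "ReducedModel",
    "ClusterResult",
    "SubModelSchedule",
    "Window",
    "ErrorReport",
    "BoundEstimate",
    "eliminate_always_inactive",
    "choose_cluster_count",
    "cluster_switching_times",
    "ckmeans_1d",
    "build_schedule",
    "global_relative_error",
    "windowed_errors",
    "average_variable_error",
    "theoretical_error_bound",
]


@dataclass
class ReducedModel:
    """The base model with a keep/drop mask over its processes."""

    base: ProcessModel
    dropped: frozenset[tuple[int, int]]
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def kept(self) -> tuple[tuple[int, int], ...]:
        return tuple(idx for idx in self.base.term_index if idx not in self.dropped)

    def to_model(self) -> ProcessModel:
        return self.base.drop_terms(self.dropped)


def eliminate_always_inactive(model: ProcessModel, profile: ActivityProfile) -> ReducedModel:
    """Drop exactly the processes whose weight never reaches the threshold."""
    dead = profile.always_inactive
    return ReducedModel(base=model, dropped=dead,
                        provenance={idx: "always-inactive" for idx in dead})


def choose_cluster_count(profile: ActivityProfile) -> int:
    """Half of the active-count range, rounded half away from zero.

    The spread between the most and least busy instants measures how much
    the set of active processes reorganises over the horizon; half that
    spread is used as the number of switching-time clusters.
    """
    n = profile.n_act
    spread = int(n.max()) - int(n.min())
    return int(np.floor(spread / 2 + 0.5))


def ckmeans_1d(values: Sequence[float], z: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means by dynamic programming over contiguous partitions.

    Returns ``(assignments, means)`` with clusters numbered 1..z in
    ascending order of their means. For sorted 1-D data the optimal
    k-means partition is contiguous, so an O(z n^2) DP over split points
    gives the global optimum deterministically.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not 1 <= z <= n:
        raise ValueError(f"cluster count z={z} must lie in [1, {n}]")
    # prefix sums for O(1) segment cost
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(a: int, b: int) -> float:  # segment x[a:b], half-open
        m = b - a
        seg = s1[b] - s1[a]
        return float(s2[b] - s2[a] - seg * seg / m)

    INF = float("inf")
    dp = np.full((z + 1, n + 1), INF)
    back = np.zeros((z + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, z + 1):
        for b in range(k, n + 1):
            best, barg = INF, k - 1
            for a in range(k - 1, b):
                c = dp[k - 1, a] + cost(a, b)
                if c < best - 1e-15:
                    best, barg = c, a
            dp[k, b], back[k, b] = best, barg
    # recover boundaries
    bounds = [n]
    b = n
    for k in range(z, 0, -1):
        b = back[k, b]
        bounds.append(b)
    bounds = bounds[::-1]
    assign_sorted = np.empty(n, dtype=int)
    means = np.empty(z)
    for k in range(z):
        a, b = bounds[k], bounds[k + 1]
        assign_sorted[a:b] = k + 1
        means[k] = x[a:b].mean()
    # map back to the caller's order
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    assignments = np.empty(n, dtype=int)
    assignments[order] = assign_sorted
    return assignments, means


@dataclass
class ClusterResult:
    """Clustered switching times and the reduced switching times."""

    z: int
    times: np.ndarray            # the clustered values, caller order
    assignments: np.ndarray      # cluster id (1..z) per value
    means: np.ndarray            # ascending cluster means = t_v^r

    def cluster_of(self, t: float) -> int:
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > 1e-9:
            raise KeyError(f"{t} is not a clustered switching time")
        return int(self.assignments[k])

    def inertia(self) -> float:
        return float(sum(((self.times[self.assignments == v + 1] - self.means[v]) ** 2).sum()
                         for v in range(self.z)))


def cluster_switching_times(S: SwitchingTimeSet, z: int, seed: int | None = None) -> ClusterResult:
    """Group the global switching-time set into ``z`` clusters.

    The 1-D k-means optimum is computed exactly by dynamic programming,
    so the result is deterministic; ``seed`` is accepted for API
    symmetry only.
    """
    times = S.times()
    if z > len(times):
        raise ValueError(f"z={z} exceeds the number of switching times ({len(times)})")
    assignments, means = ckmeans_1d(times, z)
    return ClusterResult(z=z, times=times, assignments=assignments, means=means)


@dataclass
class Window:
    """One time window of a sub-model schedule (half-open, last closed)."""

    start: float
    end: float
    dropped: frozenset[tuple[int, int]]
    provenance: dict[tuple[int, int], str]


@dataclass
class SubModelSchedule:
    """A sequence of sub-models tiling the horizon."""

    base: ProcessModel
    boundaries: np.ndarray         # t0 < t_1^r < ... < t_z^r < T
    windows: tuple[Window, ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def submodel(self, v: int) -> ProcessModel:
        """The reduced model valid on window ``v`` (1-based)."""
        return self.base.drop_terms(self.windows[v - 1].dropped)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.base.name,
            "boundaries": [float(b) for b in self.boundaries],
            "windows": [
                {"start": w.start, "end": w.end,
                 "dropped": sorted(f"f_{i},{j}" for i, j in w.dropped)}
                for w in self.windows
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _snapped_events(
    S: SwitchingTimeSet, clusters: ClusterResult
) -> dict[tuple[int, int], list[tuple[float, str]]]:
    """Per-process switching events with times snapped to cluster means.

    Two crossings of the same process falling in the same cluster would
    make the snapped timeline switch twice at one instant; such pairs
    cancel and are removed.
    """
    per_proc: dict[tuple[int, int], list[tuple[float, str]]] = {}
    for s in sorted(S.switches):
        v = clusters.cluster_of(s.time)
        snapped = float(clusters.means[v - 1])
        per_proc.setdefault(s.index, []).append((snapped, s.direction))
    for idx, events in per_proc.items():
        pruned: list[tuple[float, str]] = []
        for ev in events:
            if pruned and pruned[-1][0] == ev[0] and pruned[-1][1] != ev[1]:
                pruned.pop()      # opposite switches at one instant annihilate
            else:
                pruned.append(ev)
        per_proc[idx] = pruned
    return per_proc


def build_schedule(
    model: ProcessModel,
    profile: ActivityProfile,
    S: SwitchingTimeSet,
    clusters: ClusterResult | None,
) -> SubModelSchedule:
    """Assemble the sub-model sequence from snapped activity timelines.

    Processes with switching times in cluster v are assumed to switch
    together at the cluster mean t_v^r; a process is dropped in a window
    iff its snapped timeline is inactive throughout it. The first window
    applies the always-inactive elimination only.
    """
    t0, t1 = float(profile.grid[0]), float(profile.grid[-1])
    dead = profile.always_inactive
    if clusters is None or clusters.z == 0 or len(S) == 0:
        windows = (Window(start=t0, end=t1, dropped=dead,
                          provenance={i: "always-inactive" for i in dead}),)
        return SubModelSchedule(base=model, boundaries=np.array([t0, t1]),
                                windows=windows)

    means = [float(m) for m in clusters.means if t0 < float(m) < t1]
    boundaries = np.array([t0, *means, t1])
    events = _snapped_events(S, clusters)
    initial_active = {idx: bool(profile.active[k, 0])
                      for k, idx in enumerate(profile.index)}

    windows: list[Window] = []
    for v in range(len(boundaries) - 1):
        a, b = float(boundaries[v]), float(boundaries[v + 1])
        dropped: set[tuple[int, int]] = set(dead)
        prov = {i: "always-inactive" for i in dead}
        if v > 0:
            for idx, evs in events.items():
                if idx in dead:
                    continue
                state = initial_active[idx]
                for t_ev, direction in evs:
                    if t_ev <= a + 1e-12:
                        state = direction == "up"
                if not state:
                    dropped.add(idx)
                    prov[idx] = f"inactive in window {v + 1}"
        windows.append(Window(start=a, end=b, dropped=frozenset(dropped),
                              provenance=prov))
    return SubModelSchedule(base=model, boundaries=boundaries, windows=tuple(windows))


# ---------------------------------------------------------------------------
# Errors


def global_relative_error(
    reference: np.ndarray,
    approx: np.ndarray,
    grid: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Time-integrated relative L1 distance between two series.

    ``int |y - y_r| dt / int |y| dt`` by trapezoidal quadrature on the
    shared grid, optionally restricted to ``window``.
    """
    reference = np.asarray(reference, dtype=float)
    approx = np.asarray(approx, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if window is not None:
        a, b = window
        mask = (grid >= a - 1e-12) & (grid <= b + 1e-12)
        reference, approx, grid = reference[mask], approx[mask], grid[mask]
    denom = np.trapezoid(np.abs(reference), grid)
    if denom == 0.0:
        raise ZeroDivisionError("reference series integrates to zero on the window")
    return float(np.trapezoid(np.abs(reference - approx), grid) / denom)


@dataclass
class ErrorReport:
    """Reduction errors per output and per variable.

    ``output_errors``/``variable_errors`` are DataFrames indexed by
    window (1-based) with one column per output/variable.
    """

    output_errors: "object"
    variable_errors: "object"
    propagate: bool
    boundaries: np.ndarray
    failures: dict[int, str] = field(default_factory=dict)


def _window_grid(grid_step: float, a: float, b: float) -> np.ndarray:
    n = max(2, int(np.ceil((b - a) / grid_step)))
    return np.linspace(a, b, n + 1)


def windowed_errors(
    model: ProcessModel,
    schedule: SubModelSchedule,
    propagate: bool = False,
    params: Mapping[str, float] | None = None,
    grid_step: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    reference: Trajectory | None = None,
) -> ErrorReport:
    """Per-window errors of each sub-model against the original model.

    Every sub-model is integrated over its own window, starting either
    from the original model's state at the window start (``propagate
    False``) or from the previous sub-model's final state (``propagate
    True``); both systems are compared on the same window grid.
    """
    import pandas as pd

    t0 = float(schedule.boundaries[0])
    t1 = float(schedule.boundaries[-1])
    if reference is None:
        full = model.with_horizon(t0, t1)
        reference = simulate(full, params=params, grid_step=grid_step,
                             rtol=rtol, atol=atol)
    out_rows, var_rows, failures = {}, {}, {}
    carry_state: np.ndarray | None = None
    for v, win in enumerate(schedule.windows, start=1):
        a, b = win.start, win.end
        wgrid = _window_grid(grid_step, a, b)
        ref_states = np.vstack([np.interp(wgrid, reference.grid, row)
                                for row in reference.values])
        if propagate and carry_state is not None:
            x_start = carry_state
        else:
            x_start = reference.state_at(a)
        sub = schedule.submodel(v).with_horizon(a, b)
        try:
            approx = simulate(sub, params=params, x0=x_start, grid=wgrid,
                              rtol=rtol, atol=atol)
        except IntegrationError as exc:
            failures[v] = str(exc)
            carry_state = None
            continue
        carry_state = approx.values[:, -1]

        ref_traj = Trajectory(grid=wgrid, values=ref_states,
                              variables=model.variables,
                              params_used=reference.params_used)
        if model.outputs:
            y_ref = evaluate_outputs(ref_traj, model.outputs)
            y_app = evaluate_outputs(approx, model.outputs)
            out_rows[v] = {o.name: global_relative_error(y_ref[o.name].to_numpy(),
                                                         y_app[o.name].to_numpy(), wgrid)
                           for o in model.outputs}
        var_rows[v] = {var: global_relative_error(ref_states[k], approx.values[k], wgrid)
                       for k, var in enumerate(model.variables)}
    output_errors = pd.DataFrame.from_dict(out_rows, orient="index") if out_rows else \
        pd.DataFrame()
    variable_errors = pd.DataFrame.from_dict(var_rows, orient="index")
    output_errors.index.name = variable_errors.index.name = "window"
    return ErrorReport(output_errors=output_errors, variable_errors=variable_errors,
                       propagate=propagate, boundaries=schedule.boundaries,
                       failures=failures)


def average_variable_error(report: ErrorReport, window: int) -> float:
    """Mean of the per-variable errors in one window."""
    return float(report.variable_errors.loc[window].mean())


# ---------------------------------------------------------------------------
# A-priori bound


@dataclass
class BoundEstimate:
    """Gronwall-type bound on the deviation caused by dropped processes."""

    L: float
    B: np.ndarray
    delta: float
    t0: float

    def bound(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        normB = float(np.linalg.norm(self.B))
        return self.delta * normB / self.L * (np.exp(self.L * (t - self.t0)) - 1.0)


def theoretical_error_bound(
    model: ProcessModel,
    dropped: Iterable[tuple[int, int]],
    domain: Mapping[str, tuple[float, float]],
    window: tuple[float, float] | None = None,
    delta: float = 0.1,
    n_samples: int = 512,
    seed: int = 0,
) -> BoundEstimate:
    """Conservative a-priori bound on ``||x(t) - y(t)||``.

    ``B_i`` bounds the total absolute flux of equation i over the state
    box ``domain``; L is a numerically estimated Lipschitz constant (the
    largest spectral norm of the Jacobian over sampled box points). The
    deviation between the full model and the model with inactive
    processes removed then satisfies
    ``||x - y|| <= delta * ||B|| / L * (exp(L (t - t0)) - 1)``.
    """
    lo = np.array([domain[v][0] for v in model.variables], dtype=float)
    hi = np.array([domain[v][1] for v in model.variables], dtype=float)
    if np.any(hi < lo):
        raise ValueError("empty domain box")
    t0, t1 = window if window is not None else model.horizon

    rng = np.random.default_rng(seed)
    pts = lo + (hi - lo) * rng.random((n_samples, len(model.variables)))
    pts = np.vstack([pts, lo, hi])
    jac = model._get_compiled("jac")
    terms = model._get_compiled("terms")
    var_of_term = np.array([i - 1 for i, _ in model.term_index])

    L = 0.0
    Bvec = np.zeros(len(model.variables))
    for t_probe in (t0, 0.5 * (t0 + t1)):
        pvec = model.param_vector(t=t_probe)
        for x in pts:
            J = np.asarray(jac(t_probe, *x, *pvec), dtype=float)
            L = max(L, float(np.linalg.norm(J, 2)))
            vals = np.abs(np.array(terms(t_probe, *x, *pvec), dtype=float))
            row_sums = np.zeros(len(model.variables))
            np.add.at(row_sums, var_of_term, vals)
            Bvec = np.maximum(Bvec, row_sums)
    if L <= 0:
        raise ValueError("estimated Lipschitz constant is not positive")
    return BoundEstimate(L=L, B=Bvec, delta=delta, t0=t0)
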