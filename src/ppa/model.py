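"""Process-decomposed ODE models and their simulation.

A model is a system ``dx_i/dt = sum_j f_ij(x, p)`` in which every additive
term ``f_ij`` (a *process*) corresponds to a biochemical or regulatory
mechanism: transcription, translation, phosphorylation, transport,
degradation, complex formation, ... Keeping the decomposition explicit is
what allows the activity analysis in :mod:`ppa.engine` to weigh each
mechanism separately and the reduction in :mod:`ppa.reduction` to switch
individual mechanisms off.

Expressions are held symbolically (sympy) so that process magnitudes,
signs, Jacobians and parameter dependencies are all available; they are
compiled once per model to fast numeric callables for integration
(scalar path) and for dense-grid evaluation (vectorised path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "ProcessTerm",
    "ProcessLink",
    "OutputSpec",
    "Forcing",
    "ProcessModel",
    "Trajectory",
    "ModelDefinitionError",
    "IntegrationError",
    "evaluate_processes",
    "simulate",
    "evaluate_outputs",
]


class ModelDefinitionError(ValueError):
    """A model references undeclared symbols or violates its schema."""


class IntegrationError(RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class ProcessTerm:
    """One signed additive term of an ODE right-hand side.

    ``expression`` is the signed term as it appears in the equation
    (``sign * rate`` with ``rate`` non-negative on the biological domain);
    ``index`` is the 1-based (variable, position) pair.
    """

    index: tuple[int, int]
    expression: sp.Expr
    sign: int
    label: str = ""

    @property
    def rate(self) -> sp.Expr:
        """The unsigned magnitude expression ``|f_ij|`` (on the domain)."""
        return self.expression if self.sign > 0 else -self.expression

    @property
    def name(self) -> str:
        i, j = self.index
        return f"f_{i},{j}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.name} = {sp.sstr(self.expression)}"


@dataclass(frozen=True)
class ProcessLink:
    """A biochemical process that appears in several equations.

    ``members`` are (variable, position) indices of the *same* flux, e.g.
    the PER–CRY association term ``k3*P_C*C_C`` feeds equations 4, 5 and 8
    of the circadian clock model.
    """

    members: frozenset[tuple[int, int]]
    label: str = ""


@dataclass(frozen=True)
class OutputSpec:
    """A named linear combination of state variables."""

    name: str
    combination: Mapping[str, float]


@dataclass(frozen=True)
class Forcing:
    """Piecewise-constant periodic multiplier on a parameter.

    ``schedule`` is a sequence of ``(start, end, factor)`` covering one
    period; the effective parameter value at time ``t`` is
    ``nominal * factor`` for the interval containing ``t mod period``.
    Storing a multiplier (rather than absolute levels) keeps the forcing
    proportional when the nominal value is perturbed.
    """

    parameter: str
    period: float
    schedule: tuple[tuple[float, float, float], ...]

    def factor_at(self, t: float) -> float:
        tau = t % self.period
        for start, end, fac in self.schedule:
            if start <= tau < end:
                return fac
        return self.schedule[-1][2]

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Discontinuity times strictly inside (t0, t1)."""
        edges = sorted({s for s, _, _ in self.schedule} | {e for _, e, _ in self.schedule})
        out = []
        k0 = math.floor(t0 / self.period) - 1
        k1 = math.ceil(t1 / self.period) + 1
        for k in range(k0, k1 + 1):
            for e in edges:
                t = k * self.period + e
                if t0 < t < t1:
                    out.append(t)
        return sorted(set(out))


@dataclass
class Trajectory:
    """A simulated solution on a time grid (hours, nM)."""

    grid: np.ndarray
    values: np.ndarray  # shape (n_vars, n_times)
    variables: tuple[str, ...]
    params_used: dict[str, float]

    def state_at(self, t: float) -> np.ndarray:
        """State vector at ``t`` by linear interpolation on the grid."""
        return np.array([np.interp(t, self.grid, row) for row in self.values])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[self.variables.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values.T, index=pd.Index(self.grid, name="time"),
                            columns=list(self.variables))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _parse_expr(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    try:
        expr = sp.sympify(text, locals=dict(symbols))
    except (sp.SympifyError, SyntaxError) as exc:
        raise ModelDefinitionError(f"cannot parse expression {text!r}: {exc}") from exc
    return expr


class ProcessModel:
    """An ODE model decomposed into signed biological processes.

    Parameters
    ----------
    variables : sequence of str
        Ordered state-variable names.
    processes : mapping variable -> sequence of (rate, sign, label)
        ``rate`` is an expression string over variables/parameters/``t``
        (non-negative on the domain); ``sign`` is +1 or -1.
    parameters : mapping name -> value
        All numeric parameters, including any that are held fixed.
    initial_state : mapping variable -> value (nM)
    horizon : (t0, T) in hours
    forcing : sequence of Forcing, optional
    links : sequence of ProcessLink, optional
    outputs : sequence of OutputSpec, optional
    """

    def __init__(
        self,
        variables: Sequence[str],
        processes: Mapping[str, Sequence[tuple[str, int, str]]],
        parameters: Mapping[str, float],
        initial_state: Mapping[str, float],
        horizon: tuple[float, float] = (0.0, 24.0),
        forcing: Sequence[Forcing] = (),
        links: Sequence[ProcessLink] = (),
        outputs: Sequence[OutputSpec] = (),
        name: str = "model",
        descriptions: Mapping[str, str] | None = None,
        parameter_units: Mapping[str, str] | None = None,
        fixed_parameters: Iterable[str] = (),
        allow_empty_equations: bool = False,
    ):
        self.name = name
        self.variables: tuple[str, ...] = tuple(variables)
        if len(set(self.variables)) != len(self.variables):
            raise ModelDefinitionError("duplicate variable names")
        self.parameters: dict[str, float] = {k: float(v) for k, v in parameters.items()}
        self.parameter_units = dict(parameter_units or {})
        self.fixed_parameters = frozenset(fixed_parameters)
        self.descriptions = dict(descriptions or {})
        self.initial_state = {v: float(initial_state[v]) for v in self.variables}
        self.horizon = (float(horizon[0]), float(horizon[1]))
        if not self.horizon[0] < self.horizon[1]:
            raise ModelDefinitionError("horizon must satisfy t0 < T")
        self.forcing: tuple[Forcing, ...] = tuple(forcing)
        self.outputs: tuple[OutputSpec, ...] = tuple(outputs)

        self._var_syms = {v: sp.Symbol(v) for v in self.variables}
        self._par_syms = {p: sp.Symbol(p) for p in self.parameters}
        clash = set(self._var_syms) & set(self._par_syms)
        if clash:
            raise ModelDefinitionError(f"names used as both variable and parameter: {clash}")
        self._t = sp.Symbol("t")
        table = {**self._var_syms, **self._par_syms, "t": self._t}

        terms: list[tuple[ProcessTerm, ...]] = []
        for i, v in enumerate(self.variables, start=1):
            spec = processes.get(v, ())
            if not spec and not allow_empty_equations:
                raise ModelDefinitionError(f"equation for {v!r} declares no process")
            row = []
            for j, (rate_text, sign, label) in enumerate(spec, start=1):
                if sign not in (+1, -1):
                    raise ModelDefinitionError(f"sign of ({i},{j}) must be +1 or -1")
                rate = _parse_expr(rate_text, table)
                free = rate.free_symbols - set(table.values())
                if free:
                    raise ModelDefinitionError(
                        f"process ({i},{j}) references undeclared symbols {sorted(map(str, free))}")
                row.append(ProcessTerm(index=(i, j), expression=sign * rate,
                                       sign=sign, label=label))
            terms.append(tuple(row))
        self.processes: tuple[tuple[ProcessTerm, ...], ...] = tuple(terms)

        seen: set[tuple[int, int]] = set()
        all_idx = {t.index for t in self.iter_terms()}
        self.links = tuple(links)
        for link in self.links:
            for member in link.members:
                if member not in all_idx:
                    raise ModelDefinitionError(f"link member {member} not a declared process")
                if member in seen:
                    raise ModelDefinitionError(f"process {member} appears in two links")
                seen.add(member)
        for out in self.outputs:
            missing = set(out.combination) - set(self.variables)
            if missing:
                raise ModelDefinitionError(f"output {out.name!r} references unknown {missing}")

        self._param_order = tuple(self.parameters)
        self._compiled: dict[str, Callable] = {}

    # -- introspection -------------------------------------------------

    def iter_terms(self) -> Iterable[ProcessTerm]:
        for row in self.processes:
            yield from row

    @property
    def term_index(self) -> tuple[tuple[int, int], ...]:
        return tuple(t.index for t in self.iter_terms())

    @property
    def n_processes(self) -> int:
        return sum(len(row) for row in self.processes)

    def term(self, i: int, j: int) -> ProcessTerm:
        return self.processes[i - 1][j - 1]

    def term_parameters(self, i: int, j: int) -> frozenset[str]:
        """Names of parameters occurring in process (i, j)."""
        syms = self.term(i, j).expression.free_symbols
        return frozenset(p for p, s in self._par_syms.items() if s in syms)

    def render_equations(self) -> str:
        """Deterministic text rendering of every equation, term by term."""
        lines = []
        for v, row in zip(self.variables, self.processes):
            parts = " ".join(
                ("+ " if t.sign > 0 else "- ") + sp.sstr(t.rate) for t in row)
            lines.append(f"d{v}/dt = {parts}")
        return "\n".join(lines)

    # -- compilation ---------------------------------------------------

    def _args(self):
        return (self._t, *[self._var_syms[v] for v in self.variables],
                *[self._par_syms[p] for p in self._param_order])

    def _get_compiled(self, kind: str) -> Callable:
        fn = self._compiled.get(kind)
        if fn is not None:
            return fn
        args = self._args()
        if kind == "rhs":
            exprs = [sp.Add(*[t.expression for t in row]) if row else sp.Integer(0)
                     for row in self.processes]
            fn = sp.lambdify(args, exprs, modules="math")
        elif kind == "jac":
            x = [self._var_syms[v] for v in self.variables]
            rhs = sp.Matrix([sp.Add(*[t.expression for t in row]) if row else sp.Integer(0)
                             for row in self.processes])
            fn = sp.lambdify(args, rhs.jacobian(x), modules="numpy")
        elif kind == "terms":
            exprs = [t.expression for t in self.iter_terms()]
            fn = sp.lambdify(args, exprs, modules="numpy")
        else:  # pragma: no cover
            raise KeyError(kind)
        self._compiled[kind] = fn
        return fn

    def param_vector(self, params: Mapping[str, float] | None = None,
                     t: float | None = None) -> tuple[float, ...]:
        """Parameter values in compilation order, with forcing applied at ``t``."""
        vals = dict(self.parameters)
        if params:
            unknown = set(params) - set(vals)
            if unknown:
                raise ModelDefinitionError(f"unknown parameters {sorted(unknown)}")
            vals.update(params)
        if t is not None:
            for f in self.forcing:
                vals[f.parameter] = vals[f.parameter] * f.factor_at(t)
        return tuple(vals[p] for p in self._param_order)

    # -- derived models ------------------------------------------------

    def _clone(self, processes: tuple[tuple[ProcessTerm, ...], ...],
               links: tuple[ProcessLink, ...], name: str) -> "ProcessModel":
        clone = object.__new__(ProcessModel)
        clone.__dict__.update(self.__dict__)
        clone.processes = processes
        clone.links = links
        clone.name = name
        clone._compiled = {}
        return clone

    def drop_terms(self, dropped: Iterable[tuple[int, int]]) -> "ProcessModel":
        """A copy of the model with the given processes removed.

        Kept terms are reused verbatim: identical expressions and the
        original (i, j) indices. Equations whose terms are all dropped
        get a zero right-hand side. Link members are restricted to kept
        processes; links left with fewer than two members are removed.
        """
        dropped = set(dropped)
        unknown = dropped - set(self.term_index)
        if unknown:
            raise ModelDefinitionError(f"cannot drop undeclared processes {sorted(unknown)}")
        if not dropped:
            return self._clone(self.processes, self.links, self.name)
        processes = tuple(
            tuple(t for t in row if t.index not in dropped)
            for row in self.processes)
        links = []
        for l in self.links:
            kept = frozenset(m for m in l.members if m not in dropped)
            if len(kept) >= 2:
                links.append(ProcessLink(members=kept, label=l.label))
        return self._clone(processes, tuple(links), f"{self.name}[reduced]")

    def with_horizon(self, t0: float, t1: float) -> "ProcessModel":
        clone = self._clone(self.processes, self.links, self.name)
        clone.horizon = (float(t0), float(t1))
        return clone

    def with_initial_state(self, x0: Mapping[str, float] | Sequence[float]) -> "ProcessModel":
        clone = self._clone(self.processes, self.links, self.name)
        if isinstance(x0, Mapping):
            clone.initial_state = {v: float(x0[v]) for v in self.variables}
        else:
            clone.initial_state = dict(zip(self.variables, map(float, x0)))
        return clone


# ---------------------------------------------------------------------------
# Operations


def evaluate_processes(
    model: ProcessModel,
    state: Mapping[str, float] | Sequence[float],
    t: float = 0.0,
    params: Mapping[str, float] | None = None,
) -> dict[tuple[int, int], float]:
    """Signed value of every process term at one state/time.

    Summing the values of row ``i`` gives ``dx_i/dt``.
    """
    if isinstance(state, Mapping):
        x = [float(state[v]) for v in model.variables]
    else:
        x = [float(s) for s in state]
    pvec = model.param_vector(params, t=t)
    vals = model._get_compiled("terms")(t, *x, *pvec)
    return {idx: float(v) for idx, v in zip(model.term_index, vals)}


def _segment_bounds(model: ProcessModel, t0: float, t1: float) -> list[float]:
    pts = {t0, t1}
    for f in model.forcing:
        pts.update(f.breakpoints(t0, t1))
    return sorted(pts)


def simulate(
    model: ProcessModel,
    params: Mapping[str, float] | None = None,
    x0: Mapping[str, float] | Sequence[float] | None = None,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    grid_step: float = 0.01,
) -> Trajectory:
    """Integrate the model on a dense time grid.

    The integration is split at forcing discontinuities (light/dark
    transitions) so the stiff solver never steps across a jump in the
    vector field. Deterministic for fixed grid and tolerances.
    """
    t0, t1 = model.horizon
    if grid is None:
        n = int(round((t1 - t0) / grid_step))
        grid = t0 + grid_step * np.arange(n + 1)
        grid[-1] = t1
    grid = np.asarray(grid, dtype=float)
    if grid[0] < t0 - 1e-12 or grid[-1] > t1 + 1e-12:
        raise ValueError("grid extends beyond the model horizon")

    if x0 is None:
        y = np.array([model.initial_state[v] for v in model.variables])
    elif isinstance(x0, Mapping):
        y = np.array([float(x0[v]) for v in model.variables])
    else:
        y = np.asarray(x0, dtype=float)

    rhs = model._get_compiled("rhs")
    jac = model._get_compiled("jac")
    out = np.empty((len(model.variables), grid.size))
    filled = 0
    segs = _segment_bounds(model, float(grid[0]), float(grid[-1]))
    for a, b in zip(segs[:-1], segs[1:]):
        pvec = model.param_vector(params, t=0.5 * (a + b))
        mask = (grid >= a - 1e-12) & (grid <= b + 1e-12) if filled == 0 else \
               (grid > a + 1e-12) & (grid <= b + 1e-12)
        t_eval = grid[mask]
        fun = lambda t, yy: rhs(t, *yy, *pvec)
        jfun = lambda t, yy: jac(t, *yy, *pvec)
        sol = solve_ivp(fun, (a, b), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol, jac=jfun, dense_output=False)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            t_fail = float(sol.t[-1]) if sol.t.size else a
            raise IntegrationError(
                f"integration of {model.name!r} failed near t={t_fail:.4g} h: {sol.message}",
                t_fail=t_fail)
        out[:, filled:filled + t_eval.size] = sol.y
        filled += t_eval.size
        # advance the segment initial state to the exact boundary
        if b < grid[-1] or t_eval.size == 0 or abs(t_eval[-1] - b) > 1e-12:
            solb = solve_ivp(fun, (a, b), y, method=method, t_eval=[b],
                             rtol=rtol, atol=atol, jac=jfun)
            if not solb.success:
                raise IntegrationError(
                    f"integration of {model.name!r} failed near t={b:.4g} h: {solb.message}",
                    t_fail=b)
            y = solb.y[:, -1]
        else:
            y = sol.y[:, -1]
    used = dict(zip(model._param_order, model.param_vector(params)))
    return Trajectory(grid=grid, values=out, variables=model.variables,
                      params_used=used)


def evaluate_outputs(traj: Trajectory, outputs: Sequence[OutputSpec]):
    """Output series (linear combinations of states) on the trajectory grid."""
    import pandas as pd

    data = {}
    for out in outputs:
        missing = set(out.combination) - set(traj.variables)
        if missing:
            raise ModelDefinitionError(f"output {out.name!r} references unknown {missing}")
        acc = np.zeros_like(traj.grid)
        for var, coeff in out.combination.items():
            acc = acc + float(coeff) * traj[var]
        data[out.name] = acc
    return pd.DataFrame(data, index=pd.Index(traj.grid, name="time"))
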