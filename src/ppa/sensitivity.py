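"""Factorial-design global sensitivity analysis of reduction errors.

Parameters are varied simultaneously at two levels (0.8x and 1.2x their
nominal value) in a regular two-level fractional factorial design of
resolution V, i.e. one in which all main effects and all two-way
interactions are estimable free of mutual aliasing. The per-run
responses are the window-wise relative errors between the original model
and a sub-model; an ANOVA with main effects and two-way interactions
splits the response variance into per-parameter shares (total
sensitivity indices), and a PCA across the per-variable errors combines
them into generalised indices weighted by component inertia.

Design construction
-------------------
A regular 2^(k-p) fraction with q = k - p base factors assigns each
factor a nonzero vector c_f in GF(2)^q; run r (r = 0..2^q-1) sets factor
f to level (-1)^<r, c_f>. The fraction has resolution V exactly when no
XOR of up to four distinct column vectors vanishes, i.e. when the set of
columns is a Sidon set in GF(2)^q. For even q a Sidon set of size
2^(q/2) - 1 is built from the Gold map x -> (x, x^3) over GF(2^(q/2))
(an almost-perfect-nonlinear map, which is what makes four-term
relations impossible); for other cases a deterministic greedy search is
used. The Sidon property is verified explicitly for every generated
design, so resolution V is asserted, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import IntegrationError, ProcessModel, Trajectory, simulate
from .reduction import SubModelSchedule, global_relative_error

__all__ = [
    "FactorialDesign",
    "AnovaDecomposition",
    "SensitivityIndices",
    "GeneralisedIndices",
    "DesignError",
    "build_two_level_design",
    "run_error_experiment",
    "anova_decompose",
    "total_sensitivity_indices",
    "pca_generalised_indices",
    "inactive_parameter_ratio",
    "window_parameter_classification",
]


class DesignError(ValueError):
    """No admissible design exists within the requested run budget."""


# -- GF(2^s) arithmetic for the Gold-map Sidon construction ----------------

_IRREDUCIBLE = {2: 0b111, 3: 0b1011, 4: 0b10011, 5: 0b100101, 6: 0b1000011,
                7: 0b10000011, 8: 0b100011011}


def _gf_mul(a: int, b: int, s: int) -> int:
    poly = _IRREDUCIBLE[s]
    r = 0
    while b:
        if b & 1:
            r ^= a
        b >>= 1
        a <<= 1
        if a >> s:
            a ^= poly
    return r


def _gold_columns(q: int) -> list[int]:
    """Sidon set {(x, x^3): x != 0} in GF(2)^q for even q."""
    s = q // 2
    if s not in _IRREDUCIBLE:
        return []
    cols = []
    for x in range(1, 1 << s):
        x3 = _gf_mul(_gf_mul(x, x, s), x, s)
        cols.append((x << s) | x3)
    return cols


def _greedy_columns(q: int) -> list[int]:
    """Deterministic greedy Sidon set in GF(2)^q: basis first, then
    candidates scanned from the top (high-weight vectors pack best)."""
    elements: list[int] = []
    sums: set[int] = set()

    def try_add(v: int) -> None:
        if v == 0 or v in sums or v in elements:
            return
        new_sums = {v ^ e for e in elements}
        if new_sums & sums or new_sums & set(elements) or len(new_sums) != len(elements):
            return
        elements.append(v)
        sums.update(new_sums)

    for v in [1 << i for i in range(q)]:
        try_add(v)
    for v in range((1 << q) - 1, 0, -1):
        try_add(v)
    return elements


def _verify_sidon(cols: Sequence[int]) -> bool:
    seen = set()
    for c in cols:
        if c == 0 or c in seen:
            return False
        seen.add(c)
    pair = set()
    cols = list(cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x = cols[i] ^ cols[j]
            if x in seen or x in pair:
                return False
            pair.add(x)
    return True


@dataclass
class FactorialDesign:
    """A balanced orthogonal two-level design with named factors."""

    factors: tuple[str, ...]
    nominal: dict[str, float]
    rel_change: float
    matrix: np.ndarray           # (runs, k) of -1/+1 (int8)
    columns: tuple[int, ...]     # GF(2)^q column vector per factor
    q: int                       # log2(number of runs)
    resolution: int = 5

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def levels(self, f: str) -> tuple[float, float]:
        p = self.nominal[f]
        return ((1 - self.rel_change) * p, (1 + self.rel_change) * p)

    def run_parameters(self, j: int) -> dict[str, float]:
        """Parameter overrides for run ``j``."""
        row = self.matrix[j]
        out = {}
        for f, code in zip(self.factors, row):
            lo, hi = self.levels(f)
            out[f] = hi if code > 0 else lo
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=list(self.factors))

    def validate(self) -> None:
        m = self.matrix.astype(float)
        if not np.all(m.sum(axis=0) == 0):
            raise DesignError("design columns are not balanced")
        gram = m.T @ m
        if not np.allclose(gram - np.diag(np.diag(gram)), 0):
            raise DesignError("design columns are not orthogonal")
        if not _verify_sidon(self.columns):
            raise DesignError("defining relation contains a word of length <= 4")


def build_two_level_design(
    factors: Sequence[str] | int,
    max_runs: int = 4096,
    nominal: Mapping[str, float] | None = None,
    rel_change: float = 0.2,
) -> FactorialDesign:
    """Smallest regular resolution-V two-level fraction for the factors.

    For k factors the base size q is increased until a Sidon column set
    of size k exists in GF(2)^q with 2^q <= max_runs; the full factorial
    (columns = singletons plus nothing) is the q = k limiting case.
    Raises :class:`DesignError`, naming the minimal feasible run count,
    when the budget is too small.
    """
    if isinstance(factors, int):
        names = tuple(f"p{i + 1}" for i in range(factors))
    else:
        names = tuple(factors)
    k = len(names)
    if k == 0:
        raise DesignError("no factors")
    nominal = dict(nominal) if nominal else {f: 1.0 for f in names}

    chosen: tuple[int, ...] | None = None
    chosen_q = None
    q = max(2, int(np.ceil(np.log2(k + 1))))
    while True:
        if q >= k:
            q = k                    # full factorial: always resolution "infinity"
            cols = [1 << i for i in range(k)]
            if (1 << q) > max_runs:
                raise DesignError(
                    f"no resolution-V design for {k} factors within {max_runs} runs; "
                    f"minimal feasible run count is {1 << q}")
            chosen, chosen_q = tuple(cols), q
            break
        candidates = _gold_columns(q) if q % 2 == 0 else []
        greedy = _greedy_columns(q)
        pool = candidates if len(candidates) >= max(k, len(greedy)) else greedy
        if len(pool) >= k and _verify_sidon(pool[:k]):
            if (1 << q) > max_runs:
                raise DesignError(
                    f"no resolution-V design for {k} factors within {max_runs} runs; "
                    f"minimal feasible run count is {1 << q}")
            chosen, chosen_q = tuple(pool[:k]), q
            break
        q += 1

    runs = 1 << chosen_q
    r = np.arange(runs, dtype=np.uint64)[:, None]
    c = np.array(chosen, dtype=np.uint64)[None, :]
    parity = np.bitwise_count(r & c) & 1
    matrix = np.where(parity == 1, -1, 1).astype(np.int8)
    design = FactorialDesign(factors=names, nominal={f: float(nominal.get(f, 1.0))
                                                     for f in names},
                             rel_change=rel_change, matrix=matrix,
                             columns=chosen, q=chosen_q,
                             resolution=5 if chosen_q < k else 2 ** 30)
    design.validate()
    return design


# -- experiment ------------------------------------------------------------


def run_error_experiment(
    model: ProcessModel,
    schedule: SubModelSchedule,
    design: FactorialDesign,
    window: int,
    targets: str = "variables",
    grid_step: float = 0.05,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    progress: bool = False,
    window_scope: str = "local",
    reference=None,
):
    """Window-wise reduction errors for every design run.

    The schedule (window boundaries, per-window masks and, under the
    default ``window_scope="local"``, the window's starting state) stays
    frozen at its nominal-parameter form; for each run both the original
    model and the window's sub-model are re-simulated with the perturbed
    parameters and compared by the windowed relative error, without
    error propagation. Failed integrations are recorded and excluded.

    ``window_scope`` controls how far a perturbation reaches:

    * ``"local"`` — each window is self-contained: both systems are
      integrated over the window only, from the nominal original's
      state at the window start, so the measured sensitivity reflects
      the window's own dynamics. This matches treating every sub-model
      as valid for its time window independently of the others.
    * ``"global"`` — the perturbed original is re-simulated from the
      horizon start and the sub-model starts from *its* state at the
      window start, so perturbations accumulate through the whole
      pre-window trajectory.
    """
    import pandas as pd

    if window_scope not in ("local", "global"):
        raise ValueError("window_scope must be 'local' or 'global'")
    win = schedule.windows[window - 1]
    a, b = win.start, win.end
    t0 = float(schedule.boundaries[0])
    n_win = max(2, int(np.ceil((b - a) / grid_step)))
    wpart = np.linspace(a, b, n_win + 1)
    if window_scope == "global" and a > t0 + 1e-12:
        n_pre = max(1, int(np.ceil((a - t0) / 0.1)))
        grid = np.concatenate([np.linspace(t0, a, n_pre + 1)[:-1], wpart])
    else:
        grid = wpart
    wmask = grid >= a - 1e-12
    wgrid = grid[wmask]

    if window_scope == "local":
        if reference is None:
            reference = simulate(model.with_horizon(t0, max(a, t0 + 1e-9)),
                                 grid_step=grid_step, rtol=1e-8, atol=1e-10)
        x_start = reference.state_at(a)
        full = model.with_horizon(a, b)
    else:
        full = model.with_horizon(t0, b)
    sub = schedule.submodel(window).with_horizon(a, b)
    if targets == "variables":
        names = list(model.variables)
    elif targets == "outputs":
        names = [o.name for o in model.outputs]
    else:
        raise ValueError("targets must be 'variables' or 'outputs'")

    rows = np.full((design.n_runs, len(names)), np.nan)
    failures: dict[int, str] = {}
    iterator = range(design.n_runs)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=f"window {window}")
        except ImportError:
            pass
    for j in iterator:
        params = design.run_parameters(j)
        try:
            if window_scope == "local":
                ref = simulate(full, params=params, x0=x_start, grid=wgrid,
                               rtol=rtol, atol=atol)
            else:
                ref = simulate(full, params=params, grid=grid, rtol=rtol, atol=atol)
            approx = simulate(sub, params=params,
                              x0=ref.values[:, np.nonzero(wmask)[0][0]]
                              if window_scope == "global" else x_start,
                              grid=wgrid, rtol=rtol, atol=atol)
        except IntegrationError as exc:
            failures[j] = str(exc)
            continue
        ref_win = ref.values[:, wmask]
        if targets == "variables":
            series_ref = {v: ref_win[i] for i, v in enumerate(model.variables)}
            series_app = {v: approx.values[i] for i, v in enumerate(model.variables)}
        else:
            from .model import evaluate_outputs

            ref_traj = Trajectory(grid=wgrid, values=ref_win,
                                  variables=model.variables, params_used=ref.params_used)
            yr = evaluate_outputs(ref_traj, model.outputs)
            ya = evaluate_outputs(approx, model.outputs)
            series_ref = {n: yr[n].to_numpy() for n in names}
            series_app = {n: ya[n].to_numpy() for n in names}
        for c, nme in enumerate(names):
            rows[j, c] = global_relative_error(series_ref[nme], series_app[nme], wgrid)
    table = pd.DataFrame(rows, columns=names)
    table.attrs["failures"] = failures
    return table


# -- ANOVA and indices -----------------------------------------------------


@dataclass
class AnovaDecomposition:
    """Least-squares effect estimates and sums of squares."""

    factors: tuple[str, ...]
    grand_mean: float
    main_effects: dict[str, float]                  # half-difference coding
    interaction_effects: dict[tuple[str, str], float]
    ss_total: float
    ss_model: float
    ss_residual: float
    ss_factor: dict[str, float]
    ss_interaction: dict[tuple[str, str], float]
    n_runs: int


def anova_decompose(response: np.ndarray, design: FactorialDesign) -> AnovaDecomposition:
    """Main-effect + two-way-interaction ANOVA on an orthogonal design.

    With +-1 coding and mutually orthogonal contrast columns the
    least-squares estimate of every effect is its contrast mean and the
    sum of squares attributable to it is ``N * effect^2``.
    """
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError("response length must equal the number of design runs")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    m = design.matrix.astype(float)
    n = design.n_runs
    mu = float(y.mean())
    yc = y - mu
    ss_t = float(yc @ yc)

    mains = m.T @ yc / n                              # (k,)
    ss_f = n * mains ** 2
    inter_eff: dict[tuple[str, str], float] = {}
    ss_fk: dict[tuple[str, str], float] = {}
    k = design.n_factors
    for i in range(k):
        ci = m[:, i]
        prods = (ci[:, None] * m[:, i + 1:]) if i + 1 < k else None
        if prods is None:
            continue
        effs = prods.T @ yc / n
        for off, e in enumerate(effs):
            pair = (design.factors[i], design.factors[i + 1 + off])
            inter_eff[pair] = float(e)
            ss_fk[pair] = float(n * e ** 2)
    ss_m = float(ss_f.sum() + sum(ss_fk.values()))
    return AnovaDecomposition(
        factors=design.factors,
        grand_mean=mu,
        main_effects={f: float(e) for f, e in zip(design.factors, mains)},
        interaction_effects=inter_eff,
        ss_total=ss_t,
        ss_model=ss_m,
        ss_residual=ss_t - ss_m,
        ss_factor={f: float(s) for f, s in zip(design.factors, ss_f)},
        ss_interaction=ss_fk,
        n_runs=n,
    )


@dataclass
class SensitivityIndices:
    """Total sensitivity indices per factor."""

    factors: tuple[str, ...]
    tSI: dict[str, float]
    tSI_prime: dict[str, float]
    variance: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"tSI": pd.Series(self.tSI),
                             "tSI_prime": pd.Series(self.tSI_prime)})


def total_sensitivity_indices(decomp: AnovaDecomposition) -> SensitivityIndices:
    """tSI_f = (SS_f + sum_k SS_fk) / SS_T, and the non-normalised
    variant tSI'_f = sigma^2 * tSI_f with sigma^2 = SS_T / (N - 1)."""
    ss_t = decomp.ss_total
    var = ss_t / max(decomp.n_runs - 1, 1)
    tsi, tsi_p = {}, {}
    for f in decomp.factors:
        if ss_t <= 0.0:
            tsi[f] = 0.0
        else:
            inter = sum(s for pair, s in decomp.ss_interaction.items() if f in pair)
            tsi[f] = (decomp.ss_factor[f] + inter) / ss_t
        tsi_p[f] = var * tsi[f]
    return SensitivityIndices(factors=decomp.factors, tSI=tsi, tSI_prime=tsi_p,
                              variance=var)


@dataclass
class GeneralisedIndices:
    """PCA-weighted indices across a multivariate error response."""

    factors: tuple[str, ...]
    inertia: np.ndarray          # omega_c over all components (sums to 1)
    n_retained: int
    component_tSI: list[dict[str, float]]
    tGSI: dict[str, float]

    def top(self, k: int = 10) -> list[str]:
        return sorted(self.factors, key=lambda f: -self.tGSI[f])[:k]

    def to_frame(self):
        import pandas as pd

        return pd.Series(self.tGSI, name="tGSI").sort_values(ascending=False).to_frame()


def pca_generalised_indices(
    error_matrix,
    design: FactorialDesign,
    inertia_target: float = 0.95,
) -> GeneralisedIndices:
    """PCA (covariance, no column scaling) of the per-variable errors,
    then an ANOVA per retained component; tGSI_f = sum_c omega_c tSI^c_f.

    Components are retained up to the smallest count whose cumulated
    inertia reaches ``inertia_target``. Runs with failed simulations
    (NaN rows) must be dropped by the caller beforehand.
    """
    import pandas as pd
    from sklearn.decomposition import PCA

    X = np.asarray(error_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("error matrix contains non-finite values")
    if X.shape[0] != design.n_runs:
        raise ValueError("error matrix rows must equal design runs")

    total_var = np.var(X, axis=0, ddof=1).sum()
    if total_var == 0.0:
        zero = {f: 0.0 for f in design.factors}
        return GeneralisedIndices(factors=design.factors,
                                  inertia=np.array([1.0]), n_retained=0,
                                  component_tSI=[], tGSI=zero)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    omega = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(omega), inertia_target - 1e-12) + 1)
    n_keep = min(n_keep, omega.size)

    comp_tsi: list[dict[str, float]] = []
    tgsi = {f: 0.0 for f in design.factors}
    for c in range(n_keep):
        dec = anova_decompose(scores[:, c], design)
        tsi = total_sensitivity_indices(dec).tSI
        comp_tsi.append(tsi)
        for f in design.factors:
            tgsi[f] += float(omega[c]) * tsi[f]
    return GeneralisedIndices(factors=design.factors, inertia=omega,
                              n_retained=n_keep, component_tSI=comp_tsi, tGSI=tgsi)


def window_parameter_classification(
    model: ProcessModel,
    schedule: SubModelSchedule,
    window: int,
    varied: Iterable[str] | None = None,
) -> frozenset[str]:
    """Parameters occurring in any process dropped in the given window.

    Worst-case rule: a parameter counts as belonging to the neglected
    processes even when it also appears in kept ones.
    """
    win = schedule.windows[window - 1]
    params: set[str] = set()
    for (i, j) in win.dropped:
        params |= model.term_parameters(i, j)
    if varied is not None:
        params &= set(varied)
    return frozenset(params)


def inactive_parameter_ratio(
    gsi: GeneralisedIndices,
    inactive_params: Iterable[str],
    k: int = 10,
) -> float:
    """Share (in %) of top-k tGSI carried by neglected-process parameters."""
    if k > len(gsi.factors):
        raise ValueError("k exceeds the number of factors")
    inactive = set(inactive_params)
    top = gsi.top(k)
    total = sum(gsi.tGSI[f] for f in top)
    if total == 0.0:
        return 0.0
    hit = sum(gsi.tGSI[f] for f in top if f in inactive)
    return 100.0 * hit / total
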