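"""High-level modelling interface.

:class:`PrincipalProcessAnalysis` is built from a
:class:`~ppa.model.ProcessModel` plus analysis settings; ``fit()`` runs
simulation, weight computation, activity classification, always-inactive
elimination, switching-time clustering, schedule construction and error
quantification, and returns a :class:`PPAResults` carrying all
intermediate objects and a ``summary()`` table.

:class:`ParameterRobustness` wraps the factorial-design sensitivity
layer for one schedule window; its ``fit()`` returns a
:class:`RobustnessResults` with the sensitivity indices and the
neglected-parameter variability ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import engine, reduction, sensitivity
from .engine import AnalysisConfig
from .model import ProcessModel, simulate, evaluate_outputs

__all__ = ["PrincipalProcessAnalysis", "PPAResults",
           "ParameterRobustness", "RobustnessResults"]


class PrincipalProcessAnalysis:
    """Activity analysis of a process-decomposed ODE model.

    Parameters
    ----------
    model : ProcessModel
    delta : float
        Activity threshold in [0, 1]; 0.1 by default.
    grid_step : float
        Dense analysis grid step in hours.
    horizon : (t0, T), optional
        Overrides the model's own horizon.
    n_clusters : int, optional
        Overrides the active-count-range rule for the cluster count.
    burn_in : int
        Number of horizon-length cycles integrated before the analysis
        window. For periodically forced models whose catalogued initial
        state is a rounded snapshot of the entrained cycle, a short
        burn-in re-converges to the limit cycle so that switching times
        are free of start-up transients. The analysis window is then the
        cycle following the burn-in, re-indexed to the horizon start.
    rtol, atol : float
        Integration tolerances.
    """

    def __init__(self, model: ProcessModel, delta: float = 0.1,
                 grid_step: float = 0.01,
                 horizon: tuple[float, float] | None = None,
                 n_clusters: int | None = None,
                 burn_in: int = 0,
                 rtol: float = 1e-8, atol: float = 1e-10):
        self.model = model if horizon is None else model.with_horizon(*horizon)
        self.config = AnalysisConfig(delta=delta, grid_step=grid_step,
                                     horizon=self.model.horizon)
        self.n_clusters = n_clusters
        self.burn_in = int(burn_in)
        self.rtol = rtol
        self.atol = atol

    def fit(self, compute_errors: bool = True) -> "PPAResults":
        model = self.model
        cfg = self.config
        if self.burn_in > 0:
            t0, t1 = model.horizon
            span = t1 - t0
            warm = simulate(model.with_horizon(t0, t0 + self.burn_in * span),
                            grid_step=cfg.grid_step, rtol=self.rtol, atol=self.atol)
            model = model.with_initial_state(warm.values[:, -1])
            self.model = model
        traj = simulate(model, grid_step=cfg.grid_step,
                        rtol=self.rtol, atol=self.atol)
        weights = engine.compute_weights(model, traj)
        profile, switches = engine.classify_activity(weights, cfg)
        reduced = reduction.eliminate_always_inactive(model, profile)

        z = self.n_clusters
        if z is None:
            z = reduction.choose_cluster_count(profile)
        z = min(z, len(switches))
        clusters = (reduction.cluster_switching_times(switches, z)
                    if z >= 1 and len(switches) else None)
        schedule = reduction.build_schedule(model, profile, switches, clusters)

        global_errors = None
        window_errors = None
        if compute_errors:
            single = reduction.SubModelSchedule(
                base=model,
                boundaries=np.array(model.horizon),
                windows=(reduction.Window(start=model.horizon[0], end=model.horizon[1],
                                          dropped=reduced.dropped,
                                          provenance=dict(reduced.provenance)),))
            rep = reduction.windowed_errors(model, single, propagate=False,
                                            grid_step=cfg.grid_step,
                                            rtol=self.rtol, atol=self.atol,
                                            reference=traj)
            if not rep.output_errors.empty:
                global_errors = rep.output_errors.loc[1]
            window_errors = reduction.windowed_errors(
                model, schedule, propagate=False, grid_step=cfg.grid_step,
                rtol=self.rtol, atol=self.atol, reference=traj)
        return PPAResults(analysis=self, trajectory=traj, weights=weights,
                          profile=profile, switching_times=switches,
                          reduced=reduced, z=z, clusters=clusters,
                          schedule=schedule, global_errors=global_errors,
                          window_errors=window_errors)


@dataclass
class PPAResults:
    """Fitted results of a principal process analysis."""

    analysis: PrincipalProcessAnalysis
    trajectory: "object"
    weights: engine.WeightSeries
    profile: engine.ActivityProfile
    switching_times: engine.SwitchingTimeSet
    reduced: reduction.ReducedModel
    z: int
    clusters: reduction.ClusterResult | None
    schedule: reduction.SubModelSchedule
    global_errors: "object" = None
    window_errors: reduction.ErrorReport | None = None

    @property
    def model(self) -> ProcessModel:
        return self.analysis.model

    @property
    def always_inactive(self) -> frozenset[tuple[int, int]]:
        return self.profile.always_inactive

    @property
    def n_active_range(self) -> tuple[int, int]:
        return engine.activity_extrema(self.profile)

    def outputs(self):
        return evaluate_outputs(self.trajectory, self.model.outputs)

    def summary(self) -> str:
        model = self.model
        lo, hi = self.n_active_range
        lines = [
            "Principal Process Analysis",
            "==========================",
            f"model:                 {model.name}",
            f"horizon:               [{model.horizon[0]:g}, {model.horizon[1]:g}] h",
            f"threshold delta:       {self.analysis.config.delta:g}",
            f"processes:             {model.n_processes}",
            f"always inactive:       {len(self.always_inactive)}",
            f"switching times:       {len(self.switching_times)}",
            f"active processes:      {lo}..{hi} simultaneously",
            f"clusters (z):          {self.z}",
        ]
        if self.clusters is not None:
            means = ", ".join(f"{m:.2f}" for m in self.clusters.means)
            lines.append(f"reduced switch times:  {means} h")
        lines.append(f"sub-models:            {self.schedule.n_windows}")
        if self.global_errors is not None:
            lines.append("")
            lines.append("Global relative errors (reduced vs original):")
            for name, val in self.global_errors.items():
                lines.append(f"  {name:>6}: {val:.4f}")
        if self.window_errors is not None and not self.window_errors.output_errors.empty:
            lines.append("")
            lines.append("Per-window output errors (no propagation):")
            tab = self.window_errors.output_errors
            lines.append("  " + " ".join(f"{c:>8}" for c in ["window", *tab.columns]))
            for v, row in tab.iterrows():
                lines.append("  " + " ".join([f"{v:>8}"] +
                                             [f"{x:8.4f}" for x in row.to_numpy()]))
        return "\n".join(lines)

    def export(self, outdir) -> None:
        """Write all tabular artefacts (CSV/JSON) to a directory."""
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(out / "trajectory.csv")
        wf = self.weights.to_frame()
        wf["active"] = self.profile.active.reshape(-1)  # same (term, time) order
        wf.to_csv(out / "weights.csv", index=False)
        self.switching_times.to_frame().to_csv(out / "switching_times.csv", index=False)
        self.schedule.to_json(out / "schedule.json")
        if self.global_errors is not None:
            self.global_errors.rename("error").to_csv(out / "global_errors.csv")
        if self.window_errors is not None:
            self.window_errors.output_errors.to_csv(out / "window_output_errors.csv")
            self.window_errors.variable_errors.to_csv(out / "window_variable_errors.csv")
        summary = {
            "model": self.model.name,
            "delta": self.analysis.config.delta,
            "n_processes": self.model.n_processes,
            "n_always_inactive": len(self.always_inactive),
            "always_inactive": sorted(f"f_{i},{j}" for i, j in self.always_inactive),
            "n_switching_times": len(self.switching_times),
            "n_active_range": list(self.n_active_range),
            "z": self.z,
            "cluster_means": ([float(m) for m in self.clusters.means]
                              if self.clusters is not None else []),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


class ParameterRobustness:
    """Factorial-design sensitivity of one window's reduction error.

    Parameters
    ----------
    results : PPAResults
        A fitted analysis providing the frozen schedule.
    window : int
        1-based window index.
    max_runs : int
        Run budget for the resolution-V design.
    rel_change : float
        Two-level perturbation, default +-20%.
    top_k : int
        Number of leading parameters used in the variability ratio.
    """

    def __init__(self, results: PPAResults, window: int,
                 max_runs: int = 4096, rel_change: float = 0.2,
                 top_k: int = 10, grid_step: float = 0.05,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 window_scope: str = "local",
                 seed: int | None = None):
        self.results = results
        self.window = window
        self.max_runs = max_runs
        self.rel_change = rel_change
        self.top_k = top_k
        self.grid_step = grid_step
        self.rtol = rtol
        self.atol = atol
        self.window_scope = window_scope
        self.seed = seed
        model = results.model
        self.factors = tuple(p for p in model.parameters
                             if p not in model.fixed_parameters)

    def fit(self, progress: bool = False) -> "RobustnessResults":
        model = self.results.model
        design = sensitivity.build_two_level_design(
            self.factors, max_runs=self.max_runs,
            nominal=model.parameters, rel_change=self.rel_change)
        table = sensitivity.run_error_experiment(
            model, self.results.schedule, design, self.window,
            targets="variables", grid_step=self.grid_step,
            rtol=self.rtol, atol=self.atol, progress=progress,
            window_scope=self.window_scope,
            reference=self.results.trajectory)
        ok = np.all(np.isfinite(table.to_numpy()), axis=1)
        if not ok.all():
            # listwise exclusion of failed runs would break orthogonality;
            # replace by the column mean, which leaves contrasts unbiased
            # for the (rare) missing rows and keeps the design balanced
            filled = table.copy()
            for c in filled.columns:
                filled.loc[~ok, c] = filled.loc[ok, c].mean()
            matrix = filled.to_numpy()
        else:
            matrix = table.to_numpy()
        gsi = sensitivity.pca_generalised_indices(matrix, design)
        inactive = sensitivity.window_parameter_classification(
            model, self.results.schedule, self.window, varied=self.factors)
        ratio = sensitivity.inactive_parameter_ratio(gsi, inactive, k=self.top_k)
        return RobustnessResults(design=design, errors=table, gsi=gsi,
                                 inactive_params=inactive, ratio=ratio,
                                 window=self.window, top_k=self.top_k,
                                 n_failed=int((~ok).sum()))


@dataclass
class RobustnessResults:
    """Sensitivity indices and the neglected-parameter variability ratio."""

    design: sensitivity.FactorialDesign
    errors: "object"
    gsi: sensitivity.GeneralisedIndices
    inactive_params: frozenset[str]
    ratio: float
    window: int
    top_k: int
    n_failed: int = 0

    def summary(self) -> str:
        top = self.gsi.top(self.top_k)
        lines = [
            "Parameter robustness (factorial design + ANOVA + PCA)",
            "=====================================================",
            f"window:                {self.window}",
            f"design:                {self.design.n_runs} runs x "
            f"{self.design.n_factors} factors (resolution V)",
            f"failed runs:           {self.n_failed}",
            f"PCA components kept:   {self.gsi.n_retained} "
            f"(inertia {self.gsi.inertia[:self.gsi.n_retained].sum():.3f})",
            "",
            f"top-{self.top_k} parameters by tGSI:",
        ]
        for f in top:
            tag = "neglected-process" if f in self.inactive_params else "kept-process"
            lines.append(f"  {f:>8}: {self.gsi.tGSI[f]:.4g}  [{tag}]")
        lines.append("")
        lines.append(f"variability from neglected-process parameters: {self.ratio:.2f}%")
        return "\n".join(lines)
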