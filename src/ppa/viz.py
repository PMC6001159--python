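"""Process-activity visualisations.

Three map styles summarise an analysis:

* **Boolean Process Map** — one row per process, grouped by variable;
  a filled bar segment marks the intervals where the process is active.
* **Dynamical Process Map** — the reaction network as a graph; process
  arrows are coloured by activity in a chosen window (red = active for
  every equation sharing the process, black = inactive for every one,
  yellow = mixed).
* **3-D Process Map** — hourly-binned mean weights of one variable's
  processes, drawn as bars coloured by relative intensity.

Every figure writes a companion CSV of the plotted values next to the
image, so the content can be checked numerically rather than by pixels.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engine import ActivityProfile, SwitchingTimeSet, WeightSeries
from .model import ProcessModel

__all__ = ["MapStyle", "render_boolean_map", "render_dynamical_map",
           "render_3d_map", "hourly_mean_weights"]


@dataclass(frozen=True)
class MapStyle:
    """Colour and binning conventions shared by the maps."""

    active_color: str = "red"
    inactive_color: str = "black"
    mixed_color: str = "gold"
    bar_on: str = "black"       # Boolean map: filled = active
    bar_off: str = "white"
    bin_hours: float = 1.0

    def __post_init__(self):
        if len({self.active_color, self.inactive_color, self.mixed_color}) != 3:
            raise ValueError("map colours must be distinct")
        if self.bin_hours <= 0:
            raise ValueError("bin width must be positive")


def _companion_csv(path) -> pathlib.Path:
    p = pathlib.Path(path)
    return p.with_suffix(".csv")


def render_boolean_map(profile: ActivityProfile, S: SwitchingTimeSet | None,
                       path, style: MapStyle = MapStyle()) -> pathlib.Path:
    """Activity timeline of every process, grouped by variable."""
    if len(profile.index) == 0:
        raise ValueError("empty activity profile")
    grid = profile.grid
    n = len(profile.index)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.18 * n)))
    rows = []
    for k, (i, j) in enumerate(profile.index):
        act = profile.active[k]
        # contiguous active segments
        edges = np.flatnonzero(np.diff(act.astype(int)))
        starts = [0, *(edges + 1)]
        spans = []
        for s, e in zip(starts, [*edges, act.size - 1]):
            if act[s]:
                spans.append((grid[s], grid[e] - grid[s]))
        y = n - 1 - k
        ax.broken_barh(spans, (y + 0.1, 0.8), color=style.bar_on)
        rows.append({"process": f"f_{i},{j}",
                     "variable": profile.variables[i - 1],
                     "active_fraction": float(act.mean())})
    ax.set_yticks([n - 1 - k + 0.5 for k in range(n)])
    ax.set_yticklabels([f"f_{i},{j}" for i, j in profile.index], fontsize=5)
    ax.set_xlim(grid[0], grid[-1])
    ax.set_xlabel("time [h]")
    ax.set_title(f"Boolean Process Map (delta={profile.delta:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    import pandas as pd

    pd.DataFrame(rows).to_csv(_companion_csv(path), index=False)
    return pathlib.Path(path)


def _link_of(model: ProcessModel, idx):
    for link in model.links:
        if idx in link.members:
            return link
    return None


def render_dynamical_map(model: ProcessModel, window_mask, path,
                         style: MapStyle = MapStyle(),
                         seed: int = 0) -> pathlib.Path:
    """Network graph with activity-coloured process arrows.

    ``window_mask`` maps (variable, position) to a boolean (active in the
    window). Shared processes (declared links) are drawn once; their
    colour reflects agreement across the sharing equations.
    """
    import networkx as nx
    import pandas as pd

    g = nx.MultiDiGraph()
    for v in model.variables:
        g.add_node(v)
    rows = []
    seen_links = set()
    for term in model.iter_terms():
        i, j = term.index
        link = _link_of(model, (i, j))
        if link is not None:
            if link in seen_links:
                continue
            seen_links.add(link)
            states = [bool(window_mask.get(m, False)) for m in link.members]
            color = (style.active_color if all(states)
                     else style.inactive_color if not any(states)
                     else style.mixed_color)
            members = sorted(link.members)
            label = link.label or term.label
        else:
            state = bool(window_mask.get((i, j), False))
            color = style.active_color if state else style.inactive_color
            members = [(i, j)]
            label = term.label
        # heuristically connect source variables to the affected one
        var = model.variables[i - 1]
        srcs = sorted({s for s in term.expression.free_symbols
                       if str(s) in model.variables and str(s) != var},
                      key=str)
        src = str(srcs[0]) if srcs else var
        g.add_edge(src, var, color=color, label=label)
        rows.append({"process": ",".join(f"f_{a},{b}" for a, b in members),
                     "label": label, "color": color})

    pos = nx.spring_layout(g, seed=seed)
    fig, ax = plt.subplots(figsize=(9, 8))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_shape="s", node_size=900,
                           node_color="#dce6f2", edgecolors="black")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=6)
    for color in (style.inactive_color, style.mixed_color, style.active_color):
        edges = [(u, v) for u, v, d in g.edges(data=True) if d["color"] == color]
        nx.draw_networkx_edges(g, pos, edgelist=edges, ax=ax, edge_color=color,
                               connectionstyle="arc3,rad=0.15", arrowsize=9)
    ax.set_axis_off()
    ax.set_title("Dynamical Process Map")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(_companion_csv(path), index=False)
    return pathlib.Path(path)


def hourly_mean_weights(weights: WeightSeries, variable: int,
                        bin_hours: float = 1.0):
    """Trapezoidal mean of each process weight per time bin.

    Returns a DataFrame (bins x processes); used by the 3-D map and
    testable independently of any rendering.
    """
    import pandas as pd

    grid = weights.grid
    t0, t1 = float(grid[0]), float(grid[-1])
    if t1 - t0 < bin_hours:
        raise ValueError("horizon shorter than one bin")
    edges = np.arange(t0, t1 + 1e-9, bin_hours)
    if edges[-1] < t1 - 1e-9:
        edges = np.append(edges, t1)
    cols = {}
    for k, (i, j) in enumerate(weights.index):
        if i != variable:
            continue
        w = weights.weights[k]
        vals = []
        for a, b in zip(edges[:-1], edges[1:]):
            m = (grid >= a - 1e-12) & (grid <= b + 1e-12)
            vals.append(float(np.trapezoid(w[m], grid[m]) / (grid[m][-1] - grid[m][0])))
        cols[f"f_{i},{j}"] = vals
    if not cols:
        raise ValueError(f"no processes for variable {variable}")
    return pd.DataFrame(cols, index=pd.Index(edges[:-1], name="bin_start"))


def render_3d_map(weights: WeightSeries, variable: int, path,
                  style: MapStyle = MapStyle()) -> pathlib.Path:
    """Hourly-binned weight intensities of one variable's processes."""
    table = hourly_mean_weights(weights, variable, style.bin_hours)
    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    cmap = plt.get_cmap("viridis")
    vmax = float(table.to_numpy().max()) or 1.0
    for pk, proc in enumerate(table.columns):
        vals = table[proc].to_numpy()
        xs = table.index.to_numpy()
        ax.bar(xs, vals, zs=pk, zdir="y", width=0.8 * style.bin_hours,
               color=[cmap(v / vmax) for v in vals], edgecolor="none")
    ax.set_yticks(range(len(table.columns)))
    ax.set_yticklabels(table.columns, fontsize=6)
    ax.set_xlabel("time [h]")
    ax.set_zlabel("mean weight")
    ax.set_title(f"3-D Process Map, variable {variable}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table.to_csv(_companion_csv(path))
    return pathlib.Path(path)
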