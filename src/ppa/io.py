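"""Reading and writing model-spec configuration files.

The configuration is declarative YAML: variables, per-equation process
lists (rate expression string, sign, label), parameter values with units,
initial conditions, horizon, optional periodic forcing, shared-process
links and output definitions. See ``ppa/data/clock.yaml`` for the full
schema in use.
"""

from __future__ import annotations

from typing import Mapping

import yaml

from .model import Forcing, ModelDefinitionError, OutputSpec, ProcessLink, ProcessModel

__all__ = ["model_from_dict", "load_model", "dump_model"]


def model_from_dict(cfg: Mapping) -> ProcessModel:
    """Build a :class:`ProcessModel` from a parsed configuration mapping."""
    try:
        var_entries = cfg["variables"]
        param_entries = cfg["parameters"]
        proc_entries = cfg["processes"]
        init = cfg["initial_state"]
    except KeyError as exc:
        raise ModelDefinitionError(f"model config missing section {exc}") from exc

    variables = []
    descriptions = {}
    for entry in var_entries:
        if isinstance(entry, str):
            variables.append(entry)
        else:
            variables.append(entry["name"])
            descriptions[entry["name"]] = entry.get("description", "")

    parameters, units = {}, {}
    for name, entry in param_entries.items():
        if isinstance(entry, Mapping):
            parameters[name] = float(entry["value"])
            if "unit" in entry:
                units[name] = entry["unit"]
        else:
            parameters[name] = float(entry)

    processes = {}
    for var, rows in proc_entries.items():
        processes[var] = [(r["rate"], int(r.get("sign", 1)), r.get("label", ""))
                          for r in rows]

    forcing = [
        Forcing(parameter=f["parameter"], period=float(f["period"]),
                schedule=tuple((float(a), float(b), float(c))
                               for a, b, c in f["schedule"]))
        for f in cfg.get("forcing", ())
    ]
    links = [
        ProcessLink(members=frozenset((int(i), int(j)) for i, j in l["members"]),
                    label=l.get("label", ""))
        for l in cfg.get("links", ())
    ]
    outputs = [OutputSpec(name=o["name"], combination=dict(o["combination"]))
               for o in cfg.get("outputs", ())]

    return ProcessModel(
        variables=variables,
        processes=processes,
        parameters=parameters,
        initial_state=init,
        horizon=tuple(cfg.get("horizon", (0.0, 24.0))),
        forcing=forcing,
        links=links,
        outputs=outputs,
        name=cfg.get("name", "model"),
        descriptions=descriptions,
        parameter_units=units,
        fixed_parameters=cfg.get("fixed_parameters", ()),
    )


def load_model(path) -> ProcessModel:
    """Load a model-spec YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ModelDefinitionError(f"{path}: not a mapping")
    return model_from_dict(cfg)


def dump_model(model: ProcessModel, path) -> None:
    """Write a model back to the YAML schema (round-trippable)."""
    import sympy as sp

    cfg = {
        "name": model.name,
        "horizon": list(model.horizon),
        "variables": [{"name": v, "description": model.descriptions.get(v, "")}
                      for v in model.variables],
        "parameters": {p: ({"value": val, "unit": model.parameter_units[p]}
                           if p in model.parameter_units else {"value": val})
                       for p, val in model.parameters.items()},
        "fixed_parameters": sorted(model.fixed_parameters),
        "forcing": [{"parameter": f.parameter, "period": f.period,
                     "schedule": [list(s) for s in f.schedule]}
                    for f in model.forcing],
        "initial_state": dict(model.initial_state),
        "processes": {
            v: [{"rate": sp.sstr(t.rate), "sign": t.sign, "label": t.label}
                for t in row]
            for v, row in zip(model.variables, model.processes)
        },
        "links": [{"label": l.label, "members": [list(m) for m in sorted(l.members)]}
                  for l in model.links],
        "outputs": [{"name": o.name, "combination": dict(o.combination)}
                    for o in model.outputs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
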