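"""Packaged reference models: the circadian clock and small toy systems."""

from __future__ import annotations

from importlib import resources

import yaml

from .io import model_from_dict
from .model import ProcessModel

__all__ = ["build_clock_model", "build_toy_linear", "build_toy_feedback",
           "get_builtin", "clock_reference_analysis", "CLOCK_TERM_COUNTS"]

#: per-equation process counts of the packaged clock model
CLOCK_TERM_COUNTS = (3, 3, 3, 6, 6, 4, 4, 7, 7, 4, 4, 6, 4, 7, 4, 4)


def build_clock_model() -> ProcessModel:
    """The 16-variable mammalian circadian clock model.

    Per/Cry/Bmal1 network with parameter Set 1, the printed initial
    conditions (nM), a 12h:12h light schedule raising the Per
    transcription rate from 1.5 to 1.8 nM/h, 76 process terms, shared
    process links and the six standard outputs (M_P, M_C, M_B, P_Tot,
    C_Tot, B_Tot).
    """
    text = resources.files("ppa").joinpath("data/clock.yaml").read_text()
    model = model_from_dict(yaml.safe_load(text))
    assert model.n_processes == 76
    return model


def build_toy_linear() -> ProcessModel:
    """Two-process linear decay with a small constant production.

    ``dx/dt = c - k*x`` with ``c`` chosen so that the production weight
    stays below 0.1 along most of the transient: a minimal system whose
    activity classification has a closed-form crossing time.
    """
    return model_from_dict({
        "name": "toy-linear",
        "horizon": [0.0, 10.0],
        "variables": [{"name": "x", "description": "decaying species"}],
        "parameters": {"c": {"value": 0.05, "unit": "nM/h"},
                       "k": {"value": 1.0, "unit": "1/h"}},
        "initial_state": {"x": 1.0},
        "processes": {"x": [
            {"rate": "c", "sign": 1, "label": "basal production"},
            {"rate": "k*x", "sign": -1, "label": "first-order decay"},
        ]},
        "outputs": [{"name": "x", "combination": {"x": 1}}],
    })


def build_toy_feedback() -> ProcessModel:
    """Two-variable negative-feedback relaxation toy.

    A species represses its own production through an intermediate;
    includes a saturable degradation and a basal leak whose weight
    crosses the default threshold once during the transient, so the
    model exercises switching-time detection and window construction.
    """
    return model_from_dict({
        "name": "toy-feedback",
        "horizon": [0.0, 24.0],
        "variables": [{"name": "u", "description": "mRNA-like species"},
                      {"name": "w", "description": "protein-like repressor"}],
        "parameters": {"a": {"value": 2.0, "unit": "nM/h"},
                       "K": {"value": 1.0, "unit": "nM"},
                       "b": {"value": 0.05, "unit": "nM/h"},
                       "d": {"value": 1.0, "unit": "1/h"},
                       "s": {"value": 1.0, "unit": "1/h"},
                       "g": {"value": 0.5, "unit": "nM/h"},
                       "Km": {"value": 0.5, "unit": "nM"}},
        "initial_state": {"u": 0.1, "w": 5.0},
        "processes": {
            "u": [
                {"rate": "a*K**2/(K**2 + w**2)", "sign": 1, "label": "repressible production"},
                {"rate": "b", "sign": 1, "label": "basal leak"},
                {"rate": "d*u", "sign": -1, "label": "first-order decay"},
            ],
            "w": [
                {"rate": "s*u", "sign": 1, "label": "synthesis from u"},
                {"rate": "g*w/(Km + w)", "sign": -1, "label": "saturable degradation"},
            ],
        },
        "outputs": [{"name": "u", "combination": {"u": 1}},
                    {"name": "w", "combination": {"w": 1}}],
    })


def clock_reference_analysis(delta: float = 0.1, grid_step: float = 0.01,
                             burn_in: int = 2, compute_errors: bool = True):
    """The packaged headline analysis of the clock model.

    The catalogued initial state is a 3-decimal snapshot of the
    entrained-cycle state at lights-on; two burn-in cycles re-converge
    to the limit cycle before the one-day analysis window, so switching
    times are free of start-up transients. Returns a fitted
    :class:`~ppa.analysis.PPAResults`.
    """
    from .analysis import PrincipalProcessAnalysis

    return PrincipalProcessAnalysis(build_clock_model(), delta=delta,
                                    grid_step=grid_step,
                                    burn_in=burn_in).fit(compute_errors=compute_errors)


_BUILTINS = {
    "clock": build_clock_model,
    "toy-linear": build_toy_linear,
    "toy-feedback": build_toy_feedback,
}


def get_builtin(name: str) -> ProcessModel:
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise KeyError(f"unknown built-in model {name!r}; "
                       f"available: {sorted(_BUILTINS)}") from None
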