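"""Parameter sensitivity of the delay history-dependence attributes.

Every conductance, reversal potential and gating time constant of the
spike-generating and modulatory currents is scaled by +/-5 % and
+/-10 % (one parameter at a time, same stimulus realization).  Each
perturbed model is run under the same Poisson protocol at a constant
pump current (the minute-1 or minute-5 mean of the reference dynamic
run) and five attributes are measured: D_mean and CV-D (slow
timescale, final 20 s bin) and F_min, D_min, kappa_min of the
quadratic delay-vs-F_inst fit (fast timescale).  The sensitivity of an
attribute to a parameter is the ordinary least-squares slope of the
fractional attribute change against the fractional parameter change
across the five scale points (a slope of 1 means a 5 % parameter
change moves the attribute by 5 %).

E_Na is dynamic (Nernst), so its scale factor is applied
multiplicatively to the Nernst output.  Time-constant factors scale
the whole tau(V) curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cable_sim as cs
from .history_analysis import binned_delay_stats, fts_quadratic_fit
from .spike_metrics import build_spike_series
from .stimuli import StimulusTrain

__all__ = [
    "SCALES",
    "ATTRIBUTES",
    "default_parameters",
    "perturbed_run",
    "sensitivity_slope",
    "run_battery",
]

SCALES = (0.90, 0.95, 1.00, 1.05, 1.10)

ATTRIBUTES = ("d_mean", "cv_d", "f_min", "d_min", "kappa_min")


def default_parameters(model: cs.AxonModel) -> list[str]:
    """All override keys of a model's channels (conductances, reversals,
    gating time constants); the pump itself is excluded (small scalings
    of it barely move the attributes)."""
    params = []
    for ch in model.channels:
        params.append(f"gbar_{ch.name}")
        params.append("E_Na" if ch.dynamic_erev else f"E_{ch.name}")
        if ch.p and ch.m is not None:
            params.append(f"tau_m_{ch.name}")
        if ch.q and ch.h is not None:
            params.append(f"tau_h_{ch.name}")
    return params


def _attributes(series, epoch_s, bin_s=20.0):
    """The five STS/FTS attributes of one run."""
    sts = binned_delay_stats(series, bin_s=bin_s)
    tab = sts.table.dropna()
    last = tab.iloc[-1] if len(tab) else None
    try:
        quad = fts_quadratic_fit(series, epoch_s=epoch_s)
        f_min, d_min, kappa = quad.f_min_hz, quad.d_min_ms, quad.kappa_min
    except ValueError:
        f_min = d_min = kappa = np.nan
    return {
        "d_mean": float(last["d_mean_ms"]) if last is not None else np.nan,
        "cv_d": float(last["cv_d"]) if last is not None else np.nan,
        "f_min": f_min,
        "d_min": d_min,
        "kappa_min": kappa,
    }


def perturbed_run(variant: str, parameter: str | None, scale: float,
                  stimulus: StimulusTrain, i_pump_const: float,
                  relax_s: float = 20.0, dt: float = cs.DEFAULT_DT_MS,
                  epoch_s: tuple[float, float] | None = None) -> dict:
    """Run one perturbed model and return its attribute set.

    ``parameter=None`` (or scale 1.0) is the reference model.  The run
    is at constant pump current, so a short epoch estimates stationary
    attributes without bias.  A model that fails to spike returns NaN
    attributes (flagged missing) instead of raising.
    """
    overrides = {} if parameter is None or scale == 1.0 else {parameter: scale}
    model = cs.make_model(variant, overrides=overrides)
    t_end = stimulus.duration_ms + 100.0
    if epoch_s is None:
        epoch_s = (0.0, t_end / 1e3)
    try:
        state = cs.relax_to_rest(model, duration_s=relax_s, dt=dt,
                                 pump_const=i_pump_const)
        trace = cs.integrate(model, state, stimulus, t_end_ms=t_end, dt=dt,
                             pump_const=i_pump_const)
        series = build_spike_series(trace, stimulus)
        if len(series) < 10:
            raise cs.SimulationError("too few propagated spikes")
        return _attributes(series, epoch_s)
    except (cs.SimulationError, ValueError):
        return {a: np.nan for a in ATTRIBUTES}


def sensitivity_slope(scales, values) -> float:
    """OLS slope of fractional attribute change vs fractional parameter
    change through the five points (reference at the origin).

    Returns NaN (flagged partial) if the reference value or any
    perturbed value is missing.
    """
    scales = np.asarray(scales, dtype=float)
    values = np.asarray(values, dtype=float)
    iref = int(np.argmin(np.abs(scales - 1.0)))
    ref = values[iref]
    if not np.isfinite(ref) or ref == 0 or not np.all(np.isfinite(values)):
        return np.nan
    dx = scales - 1.0
    dy = values / ref - 1.0
    return float(np.polyfit(dx, dy, 1)[0])


def run_battery(variant: str, stimulus: StimulusTrain, i_pump_levels: dict,
                parameters: list[str] | None = None,
                scales=SCALES, relax_s: float = 20.0,
                dt: float = cs.DEFAULT_DT_MS,
                epoch_s: tuple[float, float] | None = None) -> pd.DataFrame:
    """Full sensitivity battery: long-format table of slopes.

    ``i_pump_levels`` maps a context label (e.g. ``minute1``) to a
    constant pump current.  The same stimulus realization is reused for
    every perturbed run, cancelling train-sampling variance (paired
    design).
    """
    if parameters is None:
        parameters = default_parameters(cs.make_model(variant))
    rows = []
    for label, ipump in i_pump_levels.items():
        ref = perturbed_run(variant, None, 1.0, stimulus, ipump,
                            relax_s=relax_s, dt=dt, epoch_s=epoch_s)
        for param in parameters:
            vals = {a: [] for a in ATTRIBUTES}
            for s in scales:
                att = ref if s == 1.0 else perturbed_run(
                    variant, param, s, stimulus, ipump,
                    relax_s=relax_s, dt=dt, epoch_s=epoch_s)
                for a in ATTRIBUTES:
                    vals[a].append(att[a])
            for a in ATTRIBUTES:
                slope = sensitivity_slope(scales, vals[a])
                rows.append({"parameter": param, "attribute": a,
                             "pump_context": label, "slope": slope,
                             "n_points": int(np.sum(np.isfinite(vals[a])))})
    return pd.DataFrame(rows)
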