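"""Surrogate spike-feature series with the structure the analyses assume.

The generator emulates, without the PDE solver, the statistical
structure of per-spike features during long stimulation:

- a slow exponential hyperpolarizing drift of the trough voltage V_T
  (the pump-mediated slow-timescale effect),
- a V_T elevation decaying with the preceding inter-stimulus interval
  (post-spike summation: depolarized troughs at short intervals),
- a V_P depression decaying with the preceding interval (Na+ channel
  inactivation: lower peaks at short intervals),
- a delay generated from the reciprocal-voltage law
  d = c1/V_T + c2/V_P + c3 plus additive Gaussian noise.

Because the delay law is exactly the model class of the voltage
regression, parameter recovery is testable end to end: with zero noise
the regression returns (c1, c2, c3) exactly, and fitted coefficients
stay unbiased as noise grows.  Default numeric values mimic the scale
of the simulated series (delays in the tens of ms, V_T near -70 mV,
V_P near +25 mV); they are configuration, not claims.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spike_metrics import SPIKE_COLUMNS, SpikeSeries
from .stimuli import StimulusTrain

__all__ = ["SurrogateParams", "generate_surrogate", "recovery_surrogate"]


@dataclass(frozen=True)
class SurrogateParams:
    """True parameters of the surrogate feature generator."""

    # reciprocal-voltage delay law
    c1: float = 4000.0            # ms*mV (on 1/V_T)
    c2: float = 300.0             # ms*mV (on 1/V_P)
    c3: float = 90.0              # ms offset
    # slow drift of the trough voltage (pump-like STS)
    vt_base_mv: float = -70.0
    drift_amp_mv: float = 5.0     # total hyperpolarization amplitude
    drift_tau_s: float = 120.0
    # fast kernels in the preceding ISI
    summation_amp_mv: float = 4.0     # V_T elevation at ISI -> 0
    summation_tau_ms: float = 30.0
    vp_base_mv: float = 25.0
    depression_amp_mv: float = 8.0    # V_P drop at ISI -> 0
    depression_tau_ms: float = 15.0
    #: growth of the fast kernels with the slow drift (0 = none); the
    #: hyperpolarized axon responds more strongly to the preceding
    #: interval, which is what makes delay variability grow with time
    interaction_gain: float = 1.0
    noise_sd_ms: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd_ms < 0:
            raise ValueError("noise SD must be non-negative")
        if min(self.drift_tau_s, self.summation_tau_ms, self.depression_tau_ms) <= 0:
            raise ValueError("timescales must be positive")


def _features(params: SurrogateParams, t_ms: np.ndarray, isi_ms: np.ndarray):
    drift = params.drift_amp_mv * (1.0 - np.exp(-t_ms / (params.drift_tau_s * 1e3)))
    if params.drift_amp_mv != 0.0:
        gain = 1.0 + params.interaction_gain * drift / params.drift_amp_mv
    else:
        gain = np.ones_like(t_ms)
    summ = np.where(np.isfinite(isi_ms),
                    gain * params.summation_amp_mv
                    * np.exp(-isi_ms / params.summation_tau_ms),
                    0.0)
    vt = params.vt_base_mv - drift + summ
    dep = np.where(np.isfinite(isi_ms),
                   gain * params.depression_amp_mv
                   * np.exp(-isi_ms / params.depression_tau_ms),
                   0.0)
    vp = params.vp_base_mv - dep
    return vt, vp


def generate_surrogate(params: SurrogateParams,
                       stimulus: StimulusTrain) -> SpikeSeries:
    """One surrogate spike per stimulus pulse (deterministic per seed)."""
    t = np.asarray(stimulus.onsets_ms, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("stimulus onsets must be strictly increasing")
    isi = np.concatenate([[np.nan], np.diff(t)]) if t.size else np.empty(0)
    vt, vp = _features(params, t, isi)
    if np.any(vt >= 0):
        raise ValueError("parameters drove V_T to or above 0 mV")
    rng = np.random.default_rng(params.seed)
    delay = (params.c1 / vt + params.c2 / vp + params.c3
             + rng.normal(0.0, params.noise_sd_ms, size=t.size))
    finst = 1e3 / isi
    df = pd.DataFrame({
        "t_stim_ms": t,
        "t1_ms": t + 2.0,
        "t2_ms": t + 2.0 + delay / 9.5,
        "delay_ms": delay,
        "Finst_Hz": finst,
        "VT_mV": vt,
        "VP_mV": vp,
    })
    for c in SPIKE_COLUMNS:
        if c not in df:
            df[c] = np.nan
    return SpikeSeries(df=df[SPIKE_COLUMNS],
                       meta={"generator": "surrogate", "seed": params.seed})


def recovery_surrogate(params: SurrogateParams, isi_grid_ms) -> SpikeSeries:
    """Two-pulse surrogate trials: one conditioning+test pair per ISI.

    Mirrors the paired-pulse recovery protocol; only the test spike of
    each trial carries a finite F_inst (its conditioning spike has no
    preceding interval).  The slow drift is evaluated at t = 0 for
    every trial (each trial starts from an identical state).
    """
    isis = np.asarray(isi_grid_ms, dtype=float)
    rng = np.random.default_rng(params.seed)
    rows = []
    p0 = replace(params, drift_amp_mv=0.0)
    for k, isi in enumerate(isis):
        t = np.array([0.0, isi])
        i = np.array([np.nan, isi])
        vt, vp = _features(p0, t, i)
        delay = (params.c1 / vt + params.c2 / vp + params.c3
                 + rng.normal(0.0, params.noise_sd_ms, size=2))
        for j in range(2):
            rows.append({
                "t_stim_ms": k * 20_000.0 + t[j],
                "t1_ms": k * 20_000.0 + t[j] + 2.0,
                "t2_ms": k * 20_000.0 + t[j] + 2.0 + delay[j] / 9.5,
                "delay_ms": delay[j],
                "Finst_Hz": 1e3 / i[j] if np.isfinite(i[j]) else np.nan,
                "VT_mV": vt[j],
                "VP_mV": vp[j],
            })
    df = pd.DataFrame(rows)
    for c in SPIKE_COLUMNS:
        if c not in df:
            df[c] = np.nan
    return SpikeSeries(df=df[SPIKE_COLUMNS],
                       meta={"generator": "recovery_surrogate", "seed": params.seed})
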