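"""Slow- and fast-timescale characterization of conduction delay.

The slow-timescale (STS) effect is the drift of the mean delay D_mean
and of its coefficient of variation CV-D across 20 s bins of a long
stimulation, driven by pump-mediated baseline hyperpolarization.  The
fast-timescale (FTS) effect is the non-monotonic dependence of each
spike's delay on the instantaneous stimulus frequency F_inst, captured
by a quadratic fit whose vertex gives the fastest-conduction frequency
(F_min, D_min) and whose curvature kappa_min = 2a measures the strength
of the non-monotonicity.

The recovery cycle probes the same fast timescale with a conditioning /
test pulse pair at a grid of intervals under a constant pump current:
the test spike conducts slower than the conditioning one at short
intervals (relative refractory) and faster at intermediate ones
(supernormal).  A cubic fit of the recovery curve as delay vs F_inst
serves as a predictor for Poisson-stimulation delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cable_sim as cs
from .spike_metrics import DELAY_SCALE, SpikeSeries, build_spike_series
from .stimuli import paired_pulse_set, default_isi_grid

__all__ = [
    "STSSummary",
    "FTSQuadFit",
    "RecoveryCurve",
    "binned_delay_stats",
    "fts_quadratic_fit",
    "recovery_cycle",
    "paired_pulse_predictor",
    "CubicDelayPredictor",
    "EPOCH_MINUTE_1",
    "EPOCH_MINUTE_5",
]

#: half-open stimulation-time epochs (seconds) used throughout
EPOCH_MINUTE_1 = (0.0, 60.0)
EPOCH_MINUTE_5 = (240.0, 300.0)


@dataclass
class STSSummary:
    """Per-bin delay statistics (bin width default 20 s)."""

    bin_s: float
    table: pd.DataFrame  # columns: bin_start_s, n, d_mean_ms, cv_d

    @property
    def d_mean(self) -> np.ndarray:
        return self.table["d_mean_ms"].to_numpy()

    @property
    def cv_d(self) -> np.ndarray:
        return self.table["cv_d"].to_numpy()


@dataclass
class FTSQuadFit:
    """Quadratic delay-vs-F_inst fit and its vertex descriptors.

    kappa_min is the second derivative 2a of the fit -- the geometric
    curvature at the vertex, where the slope vanishes.  Units ms/Hz^2.
    For a concave fit (a <= 0) the vertex is not a minimum and the
    descriptors are flagged invalid.
    """

    a: float
    b: float
    c: float
    n: int
    f_range_hz: tuple[float, float]
    epoch_label: str = ""

    @property
    def valid(self) -> bool:
        return self.a > 0

    @property
    def f_min_hz(self) -> float:
        return -self.b / (2.0 * self.a) if self.valid else np.nan

    @property
    def d_min_ms(self) -> float:
        return self.c - self.b ** 2 / (4.0 * self.a) if self.valid else np.nan

    @property
    def kappa_min(self) -> float:
        return 2.0 * self.a

    def predict(self, f_hz):
        f = np.asarray(f_hz, dtype=float)
        return self.a * f * f + self.b * f + self.c


@dataclass
class RecoveryCurve:
    """Test-spike velocity/delay vs conditioning-test interval.

    ``table`` columns: isi_ms, finst_hz, delay_ms (test spike, scaled),
    velocity_m_s, ok (False where the trial failed to produce a clean
    pair of propagated spikes).  ``cond_delay_ms``/``cond_velocity_m_s``
    are the conditioning-spike baselines.
    """

    table: pd.DataFrame
    cond_delay_ms: float
    cond_velocity_m_s: float
    i_pump_const: float
    meta: dict = field(default_factory=dict)

    def phases(self, tol: float = 1e-3) -> pd.DataFrame:
        """Classify each ISI as refractory/supernormal/recovered.

        ``tol`` is the relative dead band around the conditioning
        velocity within which a trial counts as recovered.
        """
        t = self.table.copy()
        v0 = self.cond_velocity_m_s
        lab = np.where(t["velocity_m_s"] < v0 * (1 - tol), "refractory",
                       np.where(t["velocity_m_s"] > v0 * (1 + tol),
                                "supernormal", "recovered"))
        t["phase"] = np.where(t["ok"], lab, "failed")
        return t


def binned_delay_stats(series: SpikeSeries, bin_s: float = 20.0,
                       t0_ms: float | None = None) -> STSSummary:
    """Mean and coefficient of variation of delay in fixed time bins.

    Bins are anchored at the start of the stimulation epoch (``t0_ms``
    defaults to the first stimulus time).  Bins with < 2 spikes get NaN
    statistics rather than zeros.
    """
    df = series.df
    if t0_ms is None:
        t0_ms = float(df["t_stim_ms"].min()) if len(df) else 0.0
    t_s = (df["t_stim_ms"].to_numpy() - t0_ms) / 1e3
    d = df["delay_ms"].to_numpy()
    n_bins = int(np.floor(np.nanmax(t_s) / bin_s)) + 1 if len(df) else 0
    rows = []
    for b in range(n_bins):
        m = (t_s >= b * bin_s) & (t_s < (b + 1) * bin_s)
        n = int(m.sum())
        if n >= 2:
            mu = float(np.mean(d[m]))
            cv = float(np.std(d[m], ddof=1) / mu)
        else:
            mu, cv = np.nan, np.nan
        rows.append({"bin_start_s": b * bin_s, "n": n, "d_mean_ms": mu, "cv_d": cv})
    return STSSummary(bin_s=bin_s, table=pd.DataFrame(rows))


def fts_quadratic_fit(series: SpikeSeries, epoch_s: tuple[float, float] | None = None,
                      t0_ms: float | None = None, label: str = "",
                      min_spikes: int = 10) -> FTSQuadFit:
    """Least-squares quadratic of delay vs F_inst over a stimulation epoch.

    Spikes without a defined F_inst (first of a protocol) are excluded.
    """
    df = series.df
    if t0_ms is None:
        t0_ms = float(df["t_stim_ms"].min()) if len(df) else 0.0
    m = np.isfinite(df["Finst_Hz"].to_numpy()) & np.isfinite(df["delay_ms"].to_numpy())
    if epoch_s is not None:
        t_s = (df["t_stim_ms"].to_numpy() - t0_ms) / 1e3
        m &= (t_s >= epoch_s[0]) & (t_s < epoch_s[1])
    f = df["Finst_Hz"].to_numpy()[m]
    d = df["delay_ms"].to_numpy()[m]
    if f.size < min_spikes:
        raise ValueError(f"need >= {min_spikes} spikes with defined F_inst, got {f.size}")
    a, b, c = np.polyfit(f, d, 2)
    return FTSQuadFit(a=float(a), b=float(b), c=float(c), n=int(f.size),
                      f_range_hz=(float(f.min()), float(f.max())), epoch_label=label)


def recovery_cycle(model: cs.AxonModel, i_pump_const: float,
                   isi_grid_ms=None, relax_s: float = 10.0,
                   dt: float = cs.DEFAULT_DT_MS,
                   state: cs.SimState | None = None) -> RecoveryCurve:
    """Paired-pulse recovery cycle at a fixed pump current.

    The pump is replaced by the constant current density
    ``i_pump_const`` (uA/cm^2) mimicking a given level of prior
    activity; [Na+]_in dynamics are suspended.  Every trial restarts
    from the same relaxed state, so trials are independent.  Velocities
    are scaled site distance / scaled delay (= physical distance over
    unscaled delay).
    """
    if isi_grid_ms is None:
        isi_grid_ms = default_isi_grid()
    if state is None:
        state = cs.relax_to_rest(model, duration_s=relax_s, dt=dt,
                                 pump_const=i_pump_const)
    trains = paired_pulse_set(isi_grid_ms)

    lead_ms = 20.0
    tail_ms = 60.0
    dist_cm = model.geometry.dx_cm  # overwritten below
    rows = []
    cond_delays = []
    for tr_stim in trains:
        isi = float(tr_stim.meta["isi_ms"])
        s = state.copy()
        shifted = tr_stim.shifted(lead_ms)
        t_end = lead_ms + isi + tail_ms
        trace = cs.integrate(model, s, shifted, t_end_ms=t_end, dt=dt,
                             pump_const=i_pump_const)
        dist_cm = trace.site_distance_cm
        try:
            ser = build_spike_series(trace, shifted)
        except ValueError:
            ser = None
        ok = ser is not None and len(ser) == 2
        if ok:
            d_cond = float(ser.df["delay_ms"].iloc[0])
            d_test = float(ser.df["delay_ms"].iloc[1])
            cond_delays.append(d_cond)
        else:
            d_test = np.nan
        rows.append({"isi_ms": isi, "finst_hz": 1e3 / isi, "delay_ms": d_test,
                     "ok": bool(ok)})

    if not cond_delays:
        raise cs.SimulationError("no successful paired-pulse trial")
    d_cond = float(np.mean(cond_delays))
    scaled_dist_m = dist_cm * DELAY_SCALE * 1e-2
    tab = pd.DataFrame(rows)
    tab["velocity_m_s"] = scaled_dist_m / (tab["delay_ms"] * 1e-3)
    return RecoveryCurve(
        table=tab, cond_delay_ms=d_cond,
        cond_velocity_m_s=scaled_dist_m / (d_cond * 1e-3),
        i_pump_const=float(i_pump_const),
        meta={"relax_s": relax_s, "dt": dt, "n_isi": len(isi_grid_ms)})


@dataclass
class CubicDelayPredictor:
    """Cubic polynomial delay(F_inst) fitted to a recovery curve.

    Prediction clamps F_inst to the fitted range (and flags those
    spikes) rather than extrapolating the cubic tail.
    """

    coeffs: np.ndarray  # np.polyfit order-3 coefficients
    f_range_hz: tuple[float, float]
    i_pump_const: float

    def predict(self, f_hz, clamp: bool = True):
        f = np.asarray(f_hz, dtype=float)
        flagged = (f < self.f_range_hz[0]) | (f > self.f_range_hz[1])
        fc = np.clip(f, *self.f_range_hz) if clamp else f
        return np.polyval(self.coeffs, fc), flagged

    def r2(self, series: SpikeSeries, include_flagged: bool = False) -> float:
        """Coefficient of determination against a series' observed delays.

        Spikes whose F_inst falls outside the fitted range are flagged
        by :meth:`predict` and excluded by default -- the cubic has no
        support there.
        """
        df = series.df
        m = np.isfinite(df["Finst_Hz"].to_numpy()) & np.isfinite(df["delay_ms"].to_numpy())
        f = df["Finst_Hz"].to_numpy()[m]
        d = df["delay_ms"].to_numpy()[m]
        pred, flagged = self.predict(f)
        if not include_flagged:
            pred, d = pred[~flagged], d[~flagged]
        ss_res = float(np.sum((d - pred) ** 2))
        ss_tot = float(np.sum((d - np.mean(d)) ** 2))
        return 1.0 - ss_res / ss_tot


def paired_pulse_predictor(curve: RecoveryCurve) -> CubicDelayPredictor:
    """Least-squares cubic of recovery-curve delay vs F_inst."""
    tab = curve.table[curve.table["ok"]]
    f = tab["finst_hz"].to_numpy()
    d = tab["delay_ms"].to_numpy()
    if f.size < 4:
        raise ValueError("need at least 4 successful trials for a cubic fit")
    coeffs = np.polyfit(f, d, 3)
    return CubicDelayPredictor(coeffs=coeffs,
                               f_range_hz=(float(f.min()), float(f.max())),
                               i_pump_const=curve.i_pump_const)
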