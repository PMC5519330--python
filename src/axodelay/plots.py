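"""Figure helpers for the standard panels.

Each function draws from the tabular results of one analysis stage and
returns the matplotlib figure; every figure has a table it is drawn
from.  Uses the non-interactive Agg backend when none is configured.
"""

from __future__ import annotations

import matplotlib

if matplotlib.get_backend().lower() not in ("agg",) and not hasattr(
        matplotlib, "_axodelay_backend_checked"):
    try:
        matplotlib.use("Agg", force=False)
    except Exception:
        pass
    matplotlib._axodelay_backend_checked = True

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["delay_overview", "recovery_plot", "sensitivity_heatmap"]


def delay_overview(series, sts=None, quad=None, t0_ms=None):
    """Delay vs time, delay vs F_inst, and the binned D_mean / CV-D.

    ``series`` is a SpikeSeries; ``sts`` (STSSummary) and ``quad``
    (FTSQuadFit) are computed from it when not given.
    """
    from .history_analysis import binned_delay_stats, fts_quadratic_fit

    df = series.df
    if t0_ms is None:
        t0_ms = float(df["t_stim_ms"].min()) if len(df) else 0.0
    if sts is None:
        sts = binned_delay_stats(series, t0_ms=t0_ms)
    if quad is None:
        try:
            quad = fts_quadratic_fit(series, t0_ms=t0_ms)
        except ValueError:
            quad = None

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    t_s = (df["t_stim_ms"] - t0_ms) / 1e3
    axes[0, 0].plot(t_s, df["delay_ms"], ".", ms=2)
    axes[0, 0].set(xlabel="stimulus time (s)", ylabel="delay (ms)")

    axes[0, 1].plot(df["Finst_Hz"], df["delay_ms"], ".", ms=2)
    if quad is not None:
        f = np.linspace(*quad.f_range_hz, 200)
        axes[0, 1].plot(f, quad.predict(f), "r-", lw=1.5)
    axes[0, 1].set(xlabel="F_inst (Hz)", ylabel="delay (ms)")

    tab = sts.table
    axes[1, 0].plot(tab["bin_start_s"], tab["d_mean_ms"], "o-")
    axes[1, 0].set(xlabel="bin start (s)", ylabel="D_mean (ms)")
    axes[1, 1].plot(tab["bin_start_s"], tab["cv_d"], "o-")
    axes[1, 1].set(xlabel="bin start (s)", ylabel="CV-D")
    fig.tight_layout()
    return fig


def recovery_plot(*curves, labels=None):
    """Recovery-cycle velocity vs ISI and delay vs F_inst panels."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for i, curve in enumerate(curves):
        lab = labels[i] if labels else f"I_pump = {curve.i_pump_const:.2f}"
        tab = curve.table[curve.table["ok"]]
        ax1.semilogx(tab["isi_ms"], tab["velocity_m_s"], "o-", ms=3, label=lab)
        ax1.axhline(curve.cond_velocity_m_s, ls="--", lw=0.8, color="grey")
        ax2.plot(tab["finst_hz"], tab["delay_ms"], "o-", ms=3, label=lab)
    ax1.set(xlabel="ISI (ms)", ylabel="velocity (m/s)")
    ax2.set(xlabel="F_inst (Hz)", ylabel="delay (ms)")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    return fig


def sensitivity_heatmap(table, pump_context=None):
    """Heatmap of sensitivity slopes (parameters x attributes)."""
    tab = table
    if pump_context is not None:
        tab = tab[tab["pump_context"] == pump_context]
    pivot = tab.pivot_table(index="parameter", columns="attribute",
                            values="slope")
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * pivot.shape[1],
                                    0.8 + 0.35 * pivot.shape[0]))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="sensitivity slope")
    fig.tight_layout()
    return fig
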