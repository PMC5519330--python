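"""Single-spike velocity equations and empirical delay regressions.

Two published closed forms estimate the conduction velocity of an
isolated spike:

- Matsumoto-Tasaki: v = sqrt(d / (8 R_total R_i C_m^2)), from the total
  membrane resistance R_total of the excited patch (the full form also
  carries kappa = R_total/R_rest, which is ~0 for full-blown spikes);
- Muratov: v = (2/3) (r^4 abar_m^3 gbar_Na h0 / (16 R_i^4 C_m^5))^(1/8),
  from the Na+ activation rate abar_m = alpha_m(E_Na) - alpha_m(V_rest)
  and the resting inactivation h0, with the pre-spike trough voltage
  V_T standing in for V_rest during repetitive activity.

Neither tracks history-dependence well; the empirical alternative is a
linear regression d = c1*x + c2*y + c3 on two per-spike features --
either reciprocal Na+ gating rates (1/alpha_m(V_T), 1/beta_h(V_P)) or
reciprocal voltages (1/V_T, 1/V_P).  Coefficients are fitted with
Powell's method (with the closed-form least-squares solution as a
cross-check: the objective is convex, both land on the same optimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .cable_sim import AxonGeometry, AxonModel
from .core_model import gate_rates, steady_state_gate
from .spike_metrics import SpikeSeries

__all__ = [
    "RegressionFit",
    "matsumoto_tasaki_velocity",
    "muratov_velocity",
    "velocity_to_delay_ms",
    "fit_linear_combination",
    "rank_rate_pairs",
    "voltage_delay_regression",
    "predict_delays_from_voltages",
    "RATE_FEATURES",
]

#: the four reciprocal Na+ gating-rate features (units ms)
RATE_FEATURES = ("inv_alpha_m", "inv_beta_m", "inv_alpha_h", "inv_beta_h")


# --------------------------------------------------------------------------
# published single-spike equations
# --------------------------------------------------------------------------

def matsumoto_tasaki_velocity(r_total_kohm_cm2, geom: AxonGeometry,
                              kappa=0.0):
    """Boundary-matching velocity estimate from excited-state resistance.

    ``r_total`` is the total membrane resistance of unit area at the
    spike peak (kOhm cm^2).  Returns m/s.  With ``kappa`` =
    R_total/R_rest the full form v = sqrt(d (1-kappa)^2 /
    (8 R_total R_i C_m^2 (1+kappa))) is used; kappa = 0 gives the
    simplified form.
    """
    r_total = np.asarray(r_total_kohm_cm2, dtype=float) * 1e3  # Ohm cm^2
    if np.any(r_total <= 0):
        raise ValueError("R_total must be positive")
    kappa = np.asarray(kappa, dtype=float)
    d_cm = 2.0 * geom.radius_cm
    cm_f = geom.cm_uf_cm2 * 1e-6  # F/cm^2
    v_cm_s = np.sqrt(d_cm * (1.0 - kappa) ** 2
                     / (8.0 * r_total * geom.ri_ohm_cm * cm_f ** 2 * (1.0 + kappa)))
    return v_cm_s * 1e-2  # m/s


def muratov_velocity(v_t, model: AxonModel, ena: float | None = None,
                     h0=None):
    """Analytic Hodgkin-Huxley velocity estimate from Na+ gating at rest.

    ``v_t`` (mV) is the trough voltage standing in for the resting
    potential.  ``h0`` defaults to the steady-state inactivation
    h_inf(V_T); pass instantaneous values to override.  Returns m/s.
    """
    na = model.na_channel or model.channel("Na")
    if ena is None:
        ena = model.fixed_ena
    v_t = np.asarray(v_t, dtype=float)
    am_rest, _ = gate_rates(v_t, na.m)
    am_ena, _ = gate_rates(np.asarray(ena), na.m)
    abar_m = (am_ena - am_rest) * 1e3          # 1/s
    if h0 is None:
        h0 = steady_state_gate(v_t, na.h)
    h0 = np.asarray(h0, dtype=float)
    if np.any(abar_m <= 0) or np.any(h0 <= 0):
        raise ValueError("abar_m and h0 must be positive below threshold")
    geom = model.geometry
    r_m = geom.radius_cm * 1e-2                # m
    gna = na.gbar * 10.0                       # mS/cm^2 -> S/m^2
    ri = geom.ri_ohm_cm * 1e-2                 # Ohm m
    cm = geom.cm_uf_cm2 * 1e-2                 # uF/cm^2 -> F/m^2
    core = (r_m ** 4 * abar_m ** 3 * gna * h0) / (16.0 * ri ** 4 * cm ** 5)
    return (2.0 / 3.0) * core ** 0.125


def velocity_to_delay_ms(v_m_s, site_distance_cm: float,
                         scale: float = 9.5):
    """Scaled conduction delay implied by a velocity over the site span."""
    return scale * (site_distance_cm * 1e-2 / np.asarray(v_m_s, dtype=float)) * 1e3


# --------------------------------------------------------------------------
# empirical two-feature regression
# --------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """d = c1*x + c2*y + c3 with goodness of fit.

    ``kind`` names the feature pair (e.g. ``rate_pair`` or
    ``voltage_pair``); single-variable ablations replace one feature by
    a constant.
    """

    kind: str
    features: tuple[str, str]
    c1: float
    c2: float
    c3: float
    r2: float
    n: int
    collinear: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3])

    def predict(self, x, y):
        return (self.c1 * np.asarray(x, dtype=float)
                + self.c2 * np.asarray(y, dtype=float) + self.c3)

    def r2_on(self, x, y, d) -> float:
        d = np.asarray(d, dtype=float)
        pred = self.predict(x, y)
        return 1.0 - float(np.sum((d - pred) ** 2)) / float(np.sum((d - d.mean()) ** 2))


def _lstsq_fit(x, y, d):
    X = np.column_stack([x, y, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(X, d, rcond=None)
    if rank < 3:
        coef = np.linalg.pinv(X) @ d
    return coef, rank


def fit_linear_combination(x, y, delays, kind: str = "custom",
                           features: tuple[str, str] = ("x", "y"),
                           method: str = "powell",
                           min_spikes: int = 10) -> RegressionFit:
    """Fit d = c1*x + c2*y + c3 by minimizing the sum of squared errors.

    ``method='powell'`` runs Powell's conjugate-direction search from a
    zero start; the closed-form least-squares solution of this convex
    objective is always computed as well and used for the collinearity
    diagnostic (and as the result for ``method='lstsq'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(delays, dtype=float)
    m = np.isfinite(x) & np.isfinite(y) & np.isfinite(d)
    x, y, d = x[m], y[m], d[m]
    if x.size < min_spikes:
        raise ValueError(f"need >= {min_spikes} spikes, got {x.size}")

    exact, rank = _lstsq_fit(x, y, d)
    collinear = rank < 3
    if method == "powell" and not collinear:
        X = np.column_stack([x, y, np.ones_like(x)])

        def sse(c):
            r = d - X @ c
            return float(r @ r)

        res = optimize.minimize(sse, np.zeros(3), method="Powell",
                                options={"xtol": 1e-10, "ftol": 1e-12,
                                         "maxiter": 10000})
        coef = res.x
    elif method in ("powell", "lstsq"):
        coef = exact
    else:
        raise ValueError(f"unknown method {method!r}")

    pred = coef[0] * x + coef[1] * y + coef[2]
    r2 = 1.0 - float(np.sum((d - pred) ** 2)) / float(np.sum((d - d.mean()) ** 2))
    return RegressionFit(kind=kind, features=features, c1=float(coef[0]),
                         c2=float(coef[1]), c3=float(coef[2]), r2=r2,
                         n=int(x.size), collinear=collinear,
                         meta={"method": method,
                               "lstsq_coeffs": [float(v) for v in exact]})


def _sts_fts_flags(series: SpikeSeries, fit: RegressionFit, x, y) -> dict:
    """Qualitative checks: does the fit track the slow drift and the
    non-monotonic frequency dependence of the observed delays?"""
    from .history_analysis import binned_delay_stats, fts_quadratic_fit

    df = series.df
    pred = fit.predict(x, y)
    pred_series = SpikeSeries(df.assign(delay_ms=pred), dict(series.meta))
    obs_bins = binned_delay_stats(series)
    pred_bins = binned_delay_stats(pred_series)
    mo = np.isfinite(obs_bins.d_mean) & np.isfinite(pred_bins.d_mean)
    sts_ok = False
    if mo.sum() >= 3:
        t = obs_bins.table["bin_start_s"].to_numpy()[mo]
        so = np.polyfit(t, obs_bins.d_mean[mo], 1)[0]
        sp = np.polyfit(t, pred_bins.d_mean[mo], 1)[0]
        sts_ok = bool(np.sign(so) == np.sign(sp) and abs(sp) > 0.25 * abs(so))
    try:
        qo = fts_quadratic_fit(series)
        qp = fts_quadratic_fit(pred_series)
        fts_ok = bool(qo.valid and qp.valid
                      and qo.f_range_hz[0] < qp.f_min_hz < qo.f_range_hz[1])
    except ValueError:
        fts_ok = False
    return {"captures_sts": sts_ok, "captures_fts": fts_ok}


def rank_rate_pairs(series: SpikeSeries, method: str = "powell") -> list[RegressionFit]:
    """Fit all six unordered pairs of the four gating-rate features.

    Returns fits ordered by decreasing R^2; each carries qualitative
    STS/FTS capture flags in ``meta``.
    """
    df = series.df
    for c in RATE_FEATURES:
        if df[c].isna().all():
            raise ValueError("gate-rate features missing; run gate_rate_features first")
    d = df["delay_ms"].to_numpy()
    fits = []
    for fx, fy in combinations(RATE_FEATURES, 2):
        x = df[fx].to_numpy()
        y = df[fy].to_numpy()
        fit = fit_linear_combination(x, y, d, kind="rate_pair",
                                     features=(fx, fy), method=method)
        fit.meta.update(_sts_fts_flags(series, fit, x, y))
        fits.append(fit)
    return sorted(fits, key=lambda f: f.r2, reverse=True)


def voltage_delay_regression(series: SpikeSeries, method: str = "powell",
                             fix_vt: float | None = None,
                             fix_vp: float | None = None) -> RegressionFit:
    """Reciprocal-voltage regression d = c1/V_T + c2/V_P + c3.

    Voltages in mV (V_T negative, V_P positive).  ``fix_vt``/``fix_vp``
    replace one feature by a constant voltage (single-variable
    ablation); spikes with a zero voltage are skipped.  Once the model
    axon is fixed, the fitted coefficients transfer across stimulation
    protocols, so a fit from one protocol predicts another.
    """
    df = series.df
    vt = df["VT_mV"].to_numpy().copy()
    vp = df["VP_mV"].to_numpy().copy()
    with np.errstate(divide="ignore"):
        x = np.where(vt != 0, 1.0 / vt, np.nan)
        y = np.where(vp != 0, 1.0 / vp, np.nan)
    d = df["delay_ms"].to_numpy()

    if fix_vt is not None or fix_vp is not None:
        # single-variable ablation: the frozen feature is a constant and
        # would be collinear with the intercept, so it is dropped from
        # the regression (its contribution is absorbed by c3)
        if fix_vt is not None:
            kind, feat, z, frozen = "single_VP", y, x, ("VT", fix_vt)
        else:
            kind, feat, z, frozen = "single_VT", x, y, ("VP", fix_vp)
        m = np.isfinite(feat) & np.isfinite(d)
        X = np.column_stack([feat[m], np.ones(m.sum())])
        c, *_ = np.linalg.lstsq(X, d[m], rcond=None)
        pred = c[0] * feat[m] + c[1]
        r2 = 1.0 - float(np.sum((d[m] - pred) ** 2)) / float(
            np.sum((d[m] - d[m].mean()) ** 2))
        c1, c2 = (0.0, c[0]) if fix_vt is not None else (c[0], 0.0)
        fit = RegressionFit(kind=kind, features=("1/VT", "1/VP"),
                            c1=float(c1), c2=float(c2), c3=float(c[1]),
                            r2=r2, n=int(m.sum()),
                            meta={"frozen": frozen, "method": "lstsq"})
        fit.meta.update(_sts_fts_flags(series, fit, x, y))
        return fit

    fit = fit_linear_combination(x, y, d, kind="voltage_pair",
                                 features=("1/VT", "1/VP"), method=method)
    fit.meta.update(_sts_fts_flags(series, fit, x, y))
    return fit


def predict_delays_from_voltages(fit: RegressionFit, series: SpikeSeries):
    """Apply a voltage regression to another series; returns (pred, R^2)."""
    df = series.df
    x = 1.0 / df["VT_mV"].to_numpy()
    y = 1.0 / df["VP_mV"].to_numpy()
    pred = fit.predict(x, y)
    d = df["delay_ms"].to_numpy()
    m = np.isfinite(pred) & np.isfinite(d)
    r2 = 1.0 - float(np.sum((d[m] - pred[m]) ** 2)) / float(
        np.sum((d[m] - d[m].mean()) ** 2))
    return pred, r2
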