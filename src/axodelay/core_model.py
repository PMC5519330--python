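"""Ionic currents, gating kinetics and the Na+/K+ pump of the model axon.

All membrane currents are Hodgkin-Huxley form,

    I = gbar * m^p * h^q * (V - E_rev),

with first-order gates relaxing to a sigmoidal steady state
``x_inf(V) = 1/(1 + exp((V_half - V)/k))`` (``k`` > 0 for activation,
``k`` < 0 for inactivation) with a voltage-dependent time constant.
Sign convention: positive current is outward.

The electrogenic Na+/K+ pump is a sigmoid function of intracellular Na+,

    I_pump = I_max / (1 + exp((Na_half - Na_in)/Na_S)),

always outward, and drives the sodium balance

    d[Na+]_in/dt = -(I_Na + 3 I_pump) / (alpha * F * Vol)

with I_Na and I_pump expressed as total compartment currents.  The Na+
reversal potential follows the Nernst equation E_Na = 58 log10(out/in),
so sustained spiking raises [Na+]_in, activates the pump and slowly
hyperpolarizes the axon -- the mechanism behind the slow-timescale
increase of conduction delay.

Units: mV, ms, mS/cm^2, uA/cm^2, mM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TauSpec",
    "GatingSpec",
    "ChannelSpec",
    "PumpSpec",
    "ModelVariant",
    "steady_state_gate",
    "gate_time_constant",
    "gate_rates",
    "integrate_gate",
    "channel_current",
    "pump_current",
    "sodium_balance_rate",
    "sodium_nernst",
    "make_channels",
    "make_pump",
    "find_gate",
    "VARIANTS",
    "NERNST_SLOPE_MV",
]

#: slope of the Nernst relation used for Na+ (mV per decade)
NERNST_SLOPE_MV = 58.0

#: Faraday constant, C/mol
FARADAY = 96485.0


# --------------------------------------------------------------------------
# gating kinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TauSpec:
    """Voltage dependence of a gate's time constant (ms).

    Supported forms (``kind``):

    - ``const``: tau = a
    - ``cosh``: tau = a / cosh((V - v0) / s)
    - ``sigmoid``: tau = a + b / (1 + exp((V - v0) / s))
    - ``cosh_sigmoid``: tau = a/cosh((V - v0)/s) + b/(1 + exp(-(V - v1)/s1))
      (the fast Na+ activation form)
    """

    kind: str
    a: float = 0.0
    b: float = 0.0
    v0: float = 0.0
    s: float = 1.0
    v1: float = 0.0
    s1: float = 1.0

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "const":
            return np.broadcast_to(np.float64(self.a), v.shape).copy() if v.shape else np.float64(self.a)
        if self.kind == "cosh":
            return self.a / np.cosh((v - self.v0) / self.s)
        if self.kind == "sigmoid":
            return self.a + self.b / (1.0 + np.exp((v - self.v0) / self.s))
        if self.kind == "cosh_sigmoid":
            return (self.a / np.cosh((v - self.v0) / self.s)
                    + self.b / (1.0 + np.exp(-(v - self.v1) / self.s1)))
        raise ValueError(f"unknown tau kind {self.kind!r}")


@dataclass(frozen=True)
class GatingSpec:
    """One Hodgkin-Huxley gate: steady state, time constant and exponent.

    ``k`` > 0 gives an activation gate (x_inf increasing in V), ``k`` < 0
    an inactivation gate.  ``xinf_fn``/``tau_fn`` override the sigmoid /
    TauSpec forms for channels defined by rate functions (classical HH).
    ``tau_scale`` is a multiplicative factor on the whole tau(V) curve,
    used by the sensitivity analysis.
    """

    name: str
    v_half: float = 0.0
    k: float = 1.0
    tau: TauSpec | None = None
    tau_scale: float = 1.0
    xinf_fn: Callable | None = None
    tau_fn: Callable | None = None

    def xinf(self, v):
        v = np.asarray(v, dtype=float)
        if self.xinf_fn is not None:
            return self.xinf_fn(v)
        return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))

    def tau_ms(self, v):
        v = np.asarray(v, dtype=float)
        if self.tau_fn is not None:
            t = self.tau_fn(v)
        else:
            t = self.tau(v)
        return self.tau_scale * t


@dataclass(frozen=True)
class ChannelSpec:
    """One ionic current: max conductance, reversal and its gates.

    ``erev`` is the reversal potential in mV, or ``None`` for the Na+
    channel whose reversal is dynamic (Nernst from [Na+]_in).
    """

    name: str
    gbar: float
    erev: float | None
    p: int
    m: GatingSpec | None = None
    q: int = 0
    h: GatingSpec | None = None

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError("gbar must be non-negative")
        if self.p and self.m is None:
            raise ValueError(f"channel {self.name}: p > 0 requires an m gate")
        if self.q and self.h is None:
            raise ValueError(f"channel {self.name}: q > 0 requires an h gate")

    @property
    def dynamic_erev(self) -> bool:
        return self.erev is None

    def gates(self) -> list[GatingSpec]:
        out = []
        if self.p and self.m is not None:
            out.append(self.m)
        if self.q and self.h is not None:
            out.append(self.h)
        return out


@dataclass(frozen=True)
class PumpSpec:
    """Na+/K+ pump parameters and the Na+ bookkeeping constants.

    ``i_max`` is the printed maximum current density (2 mA/cm^2 =
    2000 uA/cm^2); at the operating point [Na+]_in sits far below
    ``na_half`` so the pump works on the exponential tail of the sigmoid.
    ``na_out``/``na_in_init`` set the resting Nernst potential (~+50 mV).
    """

    i_max: float = 2000.0         # uA/cm^2
    na_half: float = 78.0         # mM
    na_s: float = 2.0             # mM
    alpha: float = 7.4            # dimensionless scale factor
    vol_um3: float = 7850.0       # compartment volume
    faraday: float = FARADAY      # C/mol
    na_out: float = 479.0         # mM, held constant
    na_in_init: float = 65.0      # mM

    def __post_init__(self):
        if self.na_s <= 0 or self.vol_um3 <= 0:
            raise ValueError("na_s and vol_um3 must be positive")
        if self.na_out <= self.na_in_init:
            raise ValueError("na_out must exceed na_in at rest (E_Na > 0)")

    @property
    def rate_factor(self) -> float:
        """mM/ms per uA of total compartment current (1/(alpha*F*Vol))."""
        vol_l = self.vol_um3 * 1e-15
        return 1e-6 / (self.faraday * vol_l * self.alpha)


@dataclass(frozen=True)
class ModelVariant:
    """Named model configuration plus per-parameter scale overrides.

    ``kind`` is one of ``control``, ``DA``, ``Ih_block``, ``HH_classic``,
    ``Ks_substitute``.  ``overrides`` maps parameter names (see
    :mod:`axodelay.sensitivity`) to multiplicative scale factors.
    """

    kind: str = "control"
    overrides: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# elementary evaluations
# --------------------------------------------------------------------------

def steady_state_gate(v, gate: GatingSpec):
    """Steady-state open fraction x_inf(V) of one gate, in [0, 1]."""
    if not np.all(np.isfinite(v)):
        raise ValueError("V must be finite")
    return gate.xinf(v)


def gate_time_constant(v, gate: GatingSpec):
    """Gate time constant tau_x(V) in ms (strictly positive)."""
    if not np.all(np.isfinite(v)):
        raise ValueError("V must be finite")
    return gate.tau_ms(v)


def gate_rates(v, gate: GatingSpec):
    """Opening and closing rates (alpha, beta) in 1/ms.

    alpha = x_inf/tau, beta = (1 - x_inf)/tau, so alpha + beta = 1/tau.
    """
    xinf = steady_state_gate(v, gate)
    tau = gate_time_constant(v, gate)
    return xinf / tau, (1.0 - xinf) / tau


def integrate_gate(gate: GatingSpec, v: float, x0: float, t_ms: float,
                   dt: float = 0.025):
    """March a single gate at fixed voltage with the exponential-Euler
    update used by the cable solver.

    At fixed V the update x <- x_inf + (x - x_inf) exp(-dt/tau) is the
    exact solution of dx/dt = (x_inf - x)/tau over one step, so the
    marched value matches the closed form to round-off; the function
    exists so that property can be asserted against the analytic
    relaxation.
    """
    xinf = float(steady_state_gate(v, gate))
    tau = float(gate_time_constant(v, gate))
    n = int(round(t_ms / dt))
    decay = math.exp(-dt / tau)
    x = float(x0)
    for _ in range(n):
        x = xinf + (x - xinf) * decay
    return x


def channel_current(v, m, spec: ChannelSpec, h=1.0, erev=None):
    """Membrane current density I = gbar m^p h^q (V - E), uA/cm^2."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(m < 0) or np.any(h < 0):
        raise ValueError("gate values must be non-negative")
    e = spec.erev if erev is None else erev
    if e is None:
        raise ValueError(f"channel {spec.name} has dynamic reversal; pass erev")
    g = spec.gbar * m ** spec.p
    if spec.q:
        g = g * h ** spec.q
    return g * (np.asarray(v, dtype=float) - e)


def pump_current(na_in, spec: PumpSpec):
    """Pump current density (uA/cm^2), sigmoid in [Na+]_in, always outward."""
    na_in = np.asarray(na_in, dtype=float)
    if np.any(na_in <= 0):
        raise ValueError("[Na+]_in must be positive")
    return spec.i_max / (1.0 + np.exp((spec.na_half - na_in) / spec.na_s))


def sodium_balance_rate(i_na_ua, i_pump_ua, spec: PumpSpec):
    """d[Na+]_in/dt in mM/ms from total compartment currents in uA.

    Returns -(I_Na + 3 I_pump)/(alpha F Vol); zero when I_pump = -I_Na/3
    (the steady-state relation: the pump carries one third of the sodium
    current).
    """
    return -(np.asarray(i_na_ua, dtype=float)
             + 3.0 * np.asarray(i_pump_ua, dtype=float)) * spec.rate_factor


def sodium_nernst(na_in, na_out):
    """E_Na = 58 log10([Na+]_out/[Na+]_in), mV."""
    na_in = np.asarray(na_in, dtype=float)
    na_out = np.asarray(na_out, dtype=float)
    if np.any(na_in <= 0) or np.any(na_out <= 0):
        raise ValueError("concentrations must be positive")
    return NERNST_SLOPE_MV * np.log10(na_out / na_in)


# --------------------------------------------------------------------------
# parameter tables
# --------------------------------------------------------------------------

def _pd_gates():
    """Gating table of the PD-axon currents (steady states and taus)."""
    return {
        "Na_m": GatingSpec(
            "Na_m", v_half=-48.0, k=8.5,
            tau=TauSpec("cosh_sigmoid", a=0.132, v0=-27.0, s=7.5,
                        b=0.003, v1=-27.0, s1=5.0)),
        "Na_h": GatingSpec(
            "Na_h", v_half=-47.0, k=-6.0,
            tau=TauSpec("cosh", a=10.0, v0=-42.0, s=15.0)),
        "Kd_m": GatingSpec(
            "Kd_m", v_half=-47.0, k=10.0,
            tau=TauSpec("cosh", a=50.0, v0=-73.0, s=15.0)),
        "A_m": GatingSpec(
            "A_m", v_half=-63.0, k=15.0,
            tau=TauSpec("sigmoid", a=18.0, b=58.0, v0=-61.0, s=20.0)),
        "A_h": GatingSpec(
            "A_h", v_half=-80.0, k=-8.0,
            tau=TauSpec("const", a=50.0)),
        "h_ctrl_m": GatingSpec(
            "h_ctrl_m", v_half=-80.0, k=-5.5,
            tau=TauSpec("const", a=3700.0)),
        "h_DA_m": GatingSpec(
            "h_DA_m", v_half=-75.0, k=-12.5,
            tau=TauSpec("const", a=3800.0)),
        # same voltage dependence as Kd but 5000x slower activation
        "Ks_m": GatingSpec(
            "Ks_m", v_half=-47.0, k=10.0,
            tau=TauSpec("cosh", a=250000.0, v0=-73.0, s=15.0)),
    }


def _hh_rate_gates():
    """Classical squid-axon gates defined through alpha/beta rate functions."""

    def _vtrap(x, y):
        # x/(exp(x/y)-1) with the removable singularity handled
        x = np.asarray(x, dtype=float)
        out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0),
                       x / (np.exp(np.clip(x / y, -500, 500)) - 1.0))
        return out

    def am(v): return 0.1 * _vtrap(-(v + 40.0), 10.0)
    def bm(v): return 4.0 * np.exp(-(v + 65.0) / 18.0)
    def ah(v): return 0.07 * np.exp(-(v + 65.0) / 20.0)
    def bh(v): return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    def an(v): return 0.01 * _vtrap(-(v + 55.0), 10.0)
    def bn(v): return 0.125 * np.exp(-(v + 65.0) / 80.0)

    def gate(name, a, b):
        return GatingSpec(
            name,
            xinf_fn=lambda v, a=a, b=b: a(v) / (a(v) + b(v)),
            tau_fn=lambda v, a=a, b=b: 1.0 / (a(v) + b(v)),
        )

    return {
        "HH_m": gate("HH_m", am, bm),
        "HH_h": gate("HH_h", ah, bh),
        "HH_n": gate("HH_n", an, bn),
    }


def make_channels(variant: ModelVariant | str = "control") -> list[ChannelSpec]:
    """Channel set for a model variant (Table of printed parameters).

    ``control``: I_Na, I_Kd, I_Leak, I_A, I_h(ctrl) + dynamic pump.
    ``DA``: I_h replaced by the dopamine parameter set (gbar doubled,
    activation shifted).  ``Ih_block``: gbar_h = 0 (I_h dropped).
    ``Ks_substitute``: pump removed, slow K+ current added.
    ``HH_classic``: canonical squid parameters.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    g = _pd_gates()

    if variant.kind == "HH_classic":
        hh = _hh_rate_gates()
        return [
            ChannelSpec("Na", 120.0, 50.0, p=3, m=hh["HH_m"], q=1, h=hh["HH_h"]),
            ChannelSpec("Kd", 36.0, -77.0, p=4, m=hh["HH_n"]),
            ChannelSpec("Leak", 0.3, -54.4, p=0),
        ]

    chans = [
        ChannelSpec("Na", 14.0, None, p=3, m=g["Na_m"], q=1, h=g["Na_h"]),
        ChannelSpec("Kd", 3.0, -70.0, p=4, m=g["Kd_m"]),
        ChannelSpec("Leak", 0.125, -65.0, p=0),
        ChannelSpec("A", 5.0, -70.0, p=3, m=g["A_m"], q=1, h=g["A_h"]),
    ]
    if variant.kind == "control":
        chans.append(ChannelSpec("h", 0.05, -32.0, p=1, m=g["h_ctrl_m"]))
    elif variant.kind == "DA":
        chans.append(ChannelSpec("h", 0.1, -25.0, p=1, m=g["h_DA_m"]))
    elif variant.kind == "Ih_block":
        pass  # gbar_h = 0
    elif variant.kind == "Ks_substitute":
        chans.append(ChannelSpec("Ks", 3.0, -70.0, p=1, m=g["Ks_m"]))
    else:
        raise ValueError(f"unknown variant {variant.kind!r}")
    return chans


def make_pump(variant: ModelVariant | str = "control", **kwargs) -> PumpSpec | None:
    """Pump spec for a variant (None for HH_classic / Ks_substitute).

    The default initial [Na+]_in is variant specific: each variant rests
    stably only above a minimum standing pump current (the Na+ window
    current it must balance grows with the inward rectifier), and the
    dopamine parameter set carries a much larger resting I_h.  All
    defaults keep the resting E_Na near +50 mV.
    """
    kind = variant.kind if isinstance(variant, ModelVariant) else variant
    if kind in ("HH_classic", "Ks_substitute"):
        return None
    defaults = {"DA": 65.3, "control": 63.7, "Ih_block": 63.45}
    kwargs.setdefault("na_in_init", defaults.get(kind, 63.7))
    return PumpSpec(**kwargs)


def find_gate(channels: Sequence[ChannelSpec], channel: str, gate: str) -> GatingSpec:
    """Look up a gate (``gate`` in {'m','h'}) of a named channel."""
    for ch in channels:
        if ch.name == channel:
            if gate == "m":
                return ch.m
            if gate == "h":
                if ch.h is None:
                    raise KeyError(f"channel {channel} has no h gate")
                return ch.h
            raise KeyError(f"unknown gate {gate!r}")
    raise KeyError(f"unknown channel {channel!r}")


VARIANTS = ("control", "DA", "Ih_block", "HH_classic", "Ks_substitute")
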