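"""Unit tests of the ionic-current, gating and pump equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from axodelay import core_model as cm

CHANNELS = {c.name: c for c in cm.make_channels("control")}
KS = {c.name: c for c in cm.make_channels("Ks_substitute")}
DA = {c.name: c for c in cm.make_channels("DA")}
NA_M = CHANNELS["Na"].m
NA_H = CHANNELS["Na"].h
KD_M = CHANNELS["Kd"].m
A_M = CHANNELS["A"].m
A_H = CHANNELS["A"].h
H_M = CHANNELS["h"].m

ALL_GATES = [NA_M, NA_H, KD_M, A_M, A_H, H_M, DA["h"].m, KS["Ks"].m]


class TestSteadyStateGate:
    @pytest.mark.parametrize("gate,v,expected", [
        (NA_M, -48.0, 0.5),       # activation midpoint
        (NA_H, -47.0, 0.5),       # inactivation midpoint
        (KD_M, -47.0, 0.5),
        (A_M, -63.0, 0.5),
        (A_H, -80.0, 0.5),
        (H_M, -80.0, 0.5),
    ])
    def test_midpoints(self, gate, v, expected):
        assert cm.steady_state_gate(v, gate) == pytest.approx(expected)

    def test_sigmoid_limits(self):
        assert cm.steady_state_gate(500.0, KD_M) == pytest.approx(1.0, abs=1e-12)
        assert cm.steady_state_gate(-500.0, KD_M) == pytest.approx(0.0, abs=1e-12)
        # inactivation runs the other way
        assert cm.steady_state_gate(500.0, NA_H) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_and_tau_positive_on_grid(self):
        v = np.linspace(-120.0, 60.0, 721)
        for gate in ALL_GATES:
            x = cm.steady_state_gate(v, gate)
            assert np.all((x >= 0.0) & (x <= 1.0))
            assert np.all(cm.gate_time_constant(v, gate) > 0.0)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            cm.steady_state_gate(np.nan, NA_M)

    def test_unknown_gate_name(self):
        with pytest.raises(KeyError):
            cm.find_gate(cm.make_channels("control"), "Na", "z")
        with pytest.raises(KeyError):
            cm.find_gate(cm.make_channels("control"), "Kx", "m")


class TestTimeConstants:
    def test_na_inactivation_peak(self):
        # 10/cosh(0) at the cosh centre
        assert cm.gate_time_constant(-42.0, NA_H) == pytest.approx(10.0)

    def test_h_current_constant_tau(self):
        for v in (-100.0, -60.0, 0.0):
            assert cm.gate_time_constant(v, H_M) == pytest.approx(3700.0)
            assert cm.gate_time_constant(v, DA["h"].m) == pytest.approx(3800.0)

    def test_a_current_hyperpolarized_limit(self):
        # 18 + 58/(1+exp((V+61)/20)) -> 76 ms as V -> -inf
        assert cm.gate_time_constant(-500.0, A_M) == pytest.approx(76.0, rel=1e-9)

    def test_ks_is_5000x_slower_kd(self):
        v = np.linspace(-100, 20, 41)
        ratio = cm.gate_time_constant(v, KS["Ks"].m) / cm.gate_time_constant(v, KD_M)
        assert np.allclose(ratio, 5000.0)

    def test_na_activation_submillisecond(self):
        v = np.linspace(-120, 60, 361)
        tau = cm.gate_time_constant(v, NA_M)
        assert np.all(tau < 0.2) and np.all(tau > 0)


class TestGateRates:
    def test_rates_sum_to_inverse_tau(self):
        v = np.linspace(-100.0, 40.0, 57)
        for gate in ALL_GATES:
            a, b = cm.gate_rates(v, gate)
            assert np.allclose(a + b, 1.0 / cm.gate_time_constant(v, gate),
                               rtol=1e-12)

    def test_midpoint_rates_equal(self):
        a, b = cm.gate_rates(-48.0, NA_M)
        assert a == pytest.approx(b)
        assert a == pytest.approx(0.5 / cm.gate_time_constant(-48.0, NA_M))

    def test_na_h_rate_sum_at_tau_peak(self):
        a, b = cm.gate_rates(-42.0, NA_H)
        assert a + b == pytest.approx(0.1)  # 1/10 ms


class TestChannelCurrent:
    def test_zero_at_reversal(self):
        kd = CHANNELS["Kd"]
        assert cm.channel_current(-70.0, 0.7, kd) == pytest.approx(0.0)

    def test_ohmic_fully_open(self):
        spec = cm.ChannelSpec("X", 3.0, -70.0, p=1, m=KD_M)
        assert cm.channel_current(-20.0, 1.0, spec) == pytest.approx(150.0)

    def test_na_gated_arithmetic(self):
        na = CHANNELS["Na"]
        i = cm.channel_current(0.0, 0.5, na, h=0.5, erev=50.0)
        assert i == pytest.approx(14.0 * 0.125 * 0.5 * (-50.0))  # -43.75

    def test_negative_gate_rejected(self):
        with pytest.raises(ValueError):
            cm.channel_current(0.0, -0.1, CHANNELS["Na"], h=0.5, erev=50.0)


class TestPump:
    SPEC = cm.PumpSpec()

    def test_half_activation(self):
        assert cm.pump_current(78.0, self.SPEC) == pytest.approx(self.SPEC.i_max / 2)

    def test_saturation(self):
        assert cm.pump_current(1e4, self.SPEC) == pytest.approx(self.SPEC.i_max)

    def test_quarter_point(self):
        # invert the sigmoid: I_max/4 at Na_half - Na_S*ln(3)
        na = 78.0 - 2.0 * math.log(3.0)
        assert cm.pump_current(na, self.SPEC) == pytest.approx(self.SPEC.i_max / 4)

    def test_monotone_in_sodium(self):
        na = np.linspace(1.0, 140.0, 560)
        i = cm.pump_current(na, self.SPEC)
        assert np.all(np.diff(i) > 0)

    def test_nonpositive_sodium_rejected(self):
        with pytest.raises(ValueError):
            cm.pump_current(0.0, self.SPEC)

    def test_steady_state_one_third_relation(self):
        u = 0.37
        assert cm.sodium_balance_rate(-3 * u, u, self.SPEC) == pytest.approx(0.0)
        assert cm.sodium_balance_rate(0.0, 0.0, self.SPEC) == 0.0

    def test_alpha_scales_balance_rate(self):
        r1 = cm.sodium_balance_rate(-1.0, 0.5, cm.PumpSpec(alpha=7.4))
        r2 = cm.sodium_balance_rate(-1.0, 0.5, cm.PumpSpec(alpha=14.8))
        assert r1 == pytest.approx(2.0 * r2)


class TestNernst:
    @pytest.mark.parametrize("na_in,na_out,expected", [
        (10.0, 100.0, 58.0),
        (50.0, 50.0, 0.0),
        (4.79, 479.0, 116.0),
    ])
    def test_values(self, na_in, na_out, expected):
        assert cm.sodium_nernst(na_in, na_out) == pytest.approx(expected)

    @given(hst.floats(min_value=1e-3, max_value=1e3),
           hst.floats(min_value=1e-3, max_value=1e3),
           hst.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, a, b, k):
        assert cm.sodium_nernst(k * a, k * b) == pytest.approx(
            cm.sodium_nernst(a, b), abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cm.sodium_nernst(-1.0, 479.0)


class TestGateRelaxation:
    """Exponential-Euler marching at fixed V against the closed form."""

    @pytest.mark.parametrize("gate", [NA_M, NA_H, KD_M, A_M, A_H, H_M])
    @pytest.mark.parametrize("v", [-80.0, -55.0, -20.0])
    def test_matches_analytic_relaxation(self, gate, v):
        x0 = 0.9
        t = 3.0 * float(cm.gate_time_constant(v, gate))
        t = min(t, 50.0)
        xinf = float(cm.steady_state_gate(v, gate))
        tau = float(cm.gate_time_constant(v, gate))
        n = int(round(t / 0.025))
        exact = xinf + (x0 - xinf) * math.exp(-n * 0.025 / tau)
        marched = cm.integrate_gate(gate, v, x0, t_ms=n * 0.025, dt=0.025)
        assert marched == pytest.approx(exact, rel=1e-6)


class TestVariants:
    def test_ih_block_drops_h_current(self):
        names = [c.name for c in cm.make_channels("Ih_block")]
        assert "h" not in names
        assert set(names) == {"Na", "Kd", "Leak", "A"}

    def test_da_doubles_gh_and_shifts_activation(self):
        h_ctrl = CHANNELS["h"]
        h_da = DA["h"]
        assert h_da.gbar == pytest.approx(2 * h_ctrl.gbar)
        assert h_da.erev == -25.0
        assert h_da.m.v_half == -75.0

    def test_ks_substitute_removes_pump(self):
        assert cm.make_pump("Ks_substitute") is None
        assert cm.make_pump("HH_classic") is None
        assert cm.make_pump("control") is not None

    def test_hh_classic_squid_parameters(self):
        hh = {c.name: c for c in cm.make_channels("HH_classic")}
        assert hh["Na"].gbar == 120.0 and hh["Na"].erev == 50.0
        assert hh["Kd"].gbar == 36.0 and hh["Kd"].erev == -77.0
        assert hh["Leak"].gbar == pytest.approx(0.3)
        # canonical resting point: alpha/beta balance near -65 mV
        m = hh["Na"].m
        assert float(cm.steady_state_gate(-65.0, m)) == pytest.approx(0.053, abs=0.01)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            cm.make_channels("nonsense")

    def test_only_na_dynamic_reversal(self):
        for variant in ("control", "DA", "Ih_block"):
            chans = cm.make_channels(variant)
            dyn = [c.name for c in chans if c.dynamic_erev]
            assert dyn == ["Na"]
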