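"""Velocity equations and empirical regression tests."""

import numpy as np
import pytest

from axodelay import cable_sim as cs
from axodelay import predictors as pr
from axodelay import stimuli as st
from axodelay import synthetic_data as syn
from axodelay.core_model import gate_rates, steady_state_gate

GEOM = cs.AxonGeometry()


class TestMatsumotoTasaki:
    def test_inverse_sqrt_scaling(self):
        v1 = pr.matsumoto_tasaki_velocity(0.1, GEOM)
        v4 = pr.matsumoto_tasaki_velocity(0.4, GEOM)
        assert v4 == pytest.approx(v1 / 2.0, rel=1e-12)

    def test_kappa_zero_reduces_to_simplified(self):
        assert pr.matsumoto_tasaki_velocity(0.2, GEOM, kappa=0.0) == \
            pr.matsumoto_tasaki_velocity(0.2, GEOM)
        assert pr.matsumoto_tasaki_velocity(0.2, GEOM, kappa=0.05) < \
            pr.matsumoto_tasaki_velocity(0.2, GEOM)

    def test_dimensional_oracle(self):
        """Independent SI-unit arithmetic for the fully-open membrane."""
        g_total = 14.125e-3  # S/cm^2 (Na fully open + leak)
        r_total_ohm_cm2 = 1.0 / g_total
        d_m = 10e-6
        ri_ohm_m = 0.8
        cm_f_m2 = 0.01
        r_total_ohm_m2 = r_total_ohm_cm2 * 1e-4
        v_expect = np.sqrt(d_m / (8 * r_total_ohm_m2 * ri_ohm_m * cm_f_m2 ** 2))
        got = pr.matsumoto_tasaki_velocity(r_total_ohm_cm2 * 1e-3, GEOM)
        assert got == pytest.approx(v_expect, rel=1e-9)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            pr.matsumoto_tasaki_velocity(0.0, GEOM)


class TestMuratov:
    @pytest.fixture(scope="class")
    def model(self):
        return cs.make_model("Ih_block")

    def test_h0_eighth_power(self, model):
        v1 = pr.muratov_velocity(-70.0, model, h0=0.001)
        v2 = pr.muratov_velocity(-70.0, model, h0=0.256)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-9)

    def test_monotone_in_gna(self):
        lo = cs.make_model("Ih_block", overrides={"gbar_Na": 0.8})
        hi = cs.make_model("Ih_block", overrides={"gbar_Na": 1.2})
        assert pr.muratov_velocity(-70.0, hi) > pr.muratov_velocity(-70.0, lo)

    def test_finite_positive_over_trough_grid(self, model):
        v = pr.muratov_velocity(np.linspace(-80, -60, 21), model)
        assert np.all(np.isfinite(v)) and np.all(v > 0)
        # same order of magnitude as the simulated ~1.9 m/s conduction
        assert np.all((v > 0.5) & (v < 50.0))

    def test_uses_steady_state_inactivation_at_trough(self, model):
        na = model.na_channel
        vt = -72.0
        ena = model.fixed_ena
        am_vt, _ = gate_rates(vt, na.m)
        am_ena, _ = gate_rates(ena, na.m)
        abar = (am_ena - am_vt) * 1e3
        h0 = float(steady_state_gate(vt, na.h))
        r = model.geometry.radius_cm * 1e-2
        core = (r ** 4 * abar ** 3 * (na.gbar * 10) * h0) / (16 * 0.8 ** 4 * 0.01 ** 5)
        assert pr.muratov_velocity(vt, model) == pytest.approx(
            (2 / 3) * core ** 0.125, rel=1e-9)


class TestLinearCombinationFit:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        d = 2.5 * x - 1.25 * y + 7.0
        fit = pr.fit_linear_combination(x, y, d)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.coefficients, [2.5, -1.25, 7.0], atol=1e-6)

    def test_powell_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = 0.3 * x + rng.normal(size=300)
        d = 1.0 * x + 2.0 * y + 3.0 + rng.normal(0, 0.5, 300)
        fit = pr.fit_linear_combination(x, y, d, method="powell")
        exact = np.asarray(fit.meta["lstsq_coeffs"])
        assert np.allclose(fit.coefficients, exact, rtol=1e-6, atol=1e-8)

    def test_collinear_features_flagged(self):
        x = np.linspace(0, 1, 50)
        fit = pr.fit_linear_combination(x, 2 * x, 3 * x + 1.0)
        assert fit.collinear
        assert np.all(np.isfinite(fit.coefficients))

    def test_coefficient_recovery_unbiased_over_seeds(self):
        """1 % noise, 50 seeds: mean fitted coefficients within 3 SE of
        the generating values."""
        truth = np.array([4000.0, 300.0, 90.0])
        train = st.poisson_train(10.0, 120.0, seed=123)
        coefs = []
        for seed in range(50):
            params = syn.SurrogateParams(seed=seed, noise_sd_ms=0.4)
            ser = syn.generate_surrogate(params, train)
            fit = pr.voltage_delay_regression(ser, method="lstsq")
            coefs.append(fit.coefficients)
        coefs = np.asarray(coefs)
        se = coefs.std(axis=0, ddof=1) / np.sqrt(coefs.shape[0])
        assert np.all(np.abs(coefs.mean(axis=0) - truth) < 3 * se)

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            pr.fit_linear_combination([1, 2], [3, 4], [5, 6])


class TestVoltageRegression:
    def test_zero_noise_exact_recovery(self):
        train = st.poisson_train(10.0, 60.0, seed=9)
        ser = syn.generate_surrogate(
            syn.SurrogateParams(seed=9, noise_sd_ms=0.0), train)
        fit = pr.voltage_delay_regression(ser)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.coefficients, [4000.0, 300.0, 90.0], rtol=1e-6)

    def test_coefficients_transfer_across_protocols(self):
        params = syn.SurrogateParams(seed=4, noise_sd_ms=0.1)
        fit = pr.voltage_delay_regression(
            syn.generate_surrogate(params, st.poisson_train(10.0, 120.0, seed=4)))
        other = syn.generate_surrogate(
            params, st.poisson_train(19.0, 120.0, seed=44))
        _, r2 = pr.predict_delays_from_voltages(fit, other)
        assert r2 > 0.95

    def test_single_variable_ablations_split_the_fts(self):
        """The trough voltage carries the summation-driven delay decrease
        with F_inst (supernormal side); the peak voltage carries the
        depression-driven increase (refractory side).  Each single-variable
        ablation reproduces only its own side on single-mechanism data."""
        train = st.poisson_train(10.0, 180.0, seed=6)

        def slope_of(params, **ablate):
            ser = syn.generate_surrogate(params, train)
            df = ser.df[np.isfinite(ser.df.Finst_Hz)]
            fit = pr.voltage_delay_regression(ser, **ablate)
            pred = (fit.c1 / df.VT_mV.to_numpy()
                    + fit.c2 / df.VP_mV.to_numpy() + fit.c3)
            return np.polyfit(df.Finst_Hz.to_numpy(), pred, 1)[0]

        summation_only = syn.SurrogateParams(seed=6, noise_sd_ms=0.05,
                                             drift_amp_mv=0.0,
                                             depression_amp_mv=0.0)
        depression_only = syn.SurrogateParams(seed=6, noise_sd_ms=0.05,
                                              drift_amp_mv=0.0,
                                              summation_amp_mv=0.0)
        # V_T-only fit on summation-dominated data: delay falls with F
        assert slope_of(summation_only, fix_vp=25.0) < 0
        # V_P-only fit on depression-dominated data: delay rises with F
        assert slope_of(depression_only, fix_vt=-70.0) > 0

    def test_inv_alpha_m_linear_in_voltage_over_trough_range(self):
        """The stated justification for swapping 1/alpha_m(V_T) for V_T:
        near-linearity over the trough voltage range."""
        model = cs.make_model("Ih_block")
        v = np.linspace(-76.0, -66.0, 60)
        a, _ = gate_rates(v, model.na_channel.m)
        inv = 1.0 / a
        slope, icpt = np.polyfit(v, inv, 1)
        pred = slope * v + icpt
        r2 = 1 - np.sum((inv - pred) ** 2) / np.sum((inv - inv.mean()) ** 2)
        assert r2 > 0.98


class TestRatePairs:
    def test_six_distinct_pairs(self):
        train = st.poisson_train(10.0, 60.0, seed=8)
        ser = syn.generate_surrogate(syn.SurrogateParams(seed=8), train)
        # fill gate-rate features from the surrogate voltages
        from axodelay.spike_metrics import gate_rate_features
        ser = gate_rate_features(ser, cs.make_model("Ih_block"))
        fits = pr.rank_rate_pairs(ser, method="lstsq")
        assert len(fits) == 6
        pairs = {frozenset(f.features) for f in fits}
        assert len(pairs) == 6
        assert all(len(p) == 2 for p in pairs)
        assert all(f2.r2 <= f1.r2 for f1, f2 in zip(fits, fits[1:]))

    def test_missing_features_rejected(self):
        train = st.poisson_train(10.0, 30.0, seed=8)
        ser = syn.generate_surrogate(syn.SurrogateParams(seed=8), train)
        with pytest.raises(ValueError, match="features missing"):
            pr.rank_rate_pairs(ser)
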