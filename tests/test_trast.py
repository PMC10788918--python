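"""Stationary TRAST: pulse averaging, normalization, mixtures, fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

from trastkit.photophysics import Excitation, IsomerizationModel, preset
from trastkit.trast import (
    MixtureTrastModel,
    MonoexpTrastModel,
    MonoexpTrastParams,
    PulseTrain,
    TrastCurve,
    default_width_grid,
    fit_trast,
    interpulse_recovery,
    mean_pulse_fluorescence,
    mixture_trast_curve,
    pulse_response,
    trast_curve,
)
from trastkit.synthetic import gen_trast_curve


def dark_free_model():
    return IsomerizationModel(sigma_n=6.2e-16, sigma_biso=0.0, k_iso=0.0)


class TestPulseResponse:
    def test_no_dark_states_flat(self):
        t = np.geomspace(1e-9, 1e-3, 30)
        f = pulse_response(dark_free_model(), Excitation(1e3), np.r_[0.0, t])
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_monoexponential_decay(self, cy5):
        exc = Excitation(1e3)
        from trastkit.fcs import dark_terms_from_model

        a, tau = dark_terms_from_model(cy5, exc)
        t = np.linspace(0.0, 10 * tau, 50)
        f = pulse_response(cy5, exc, t)
        expected = 1.0 - a * (1.0 - np.exp(-t / tau))
        assert np.allclose(f, expected, rtol=1e-9)
        assert f[-1] == pytest.approx(1.0 - a, rel=1e-3)


class TestMeanPulseFluorescence:
    def test_short_pulse_limit(self):
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        assert mean_pulse_fluorescence(p, None, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_at_w_equals_tau(self):
        # 1 - A + A (1 - 1/e) = 0.834454 for A=0.45
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        assert mean_pulse_fluorescence(p, None, 12.4e-6) == pytest.approx(
            0.834454, abs=1e-6
        )

    def test_long_pulse_limit(self):
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        assert mean_pulse_fluorescence(p, None, 1.0) == pytest.approx(
            0.55, rel=1e-4
        )

    def test_nonpositive_width_rejected(self):
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        with pytest.raises(ValueError):
            mean_pulse_fluorescence(p, None, 0.0)

    def test_matches_numerical_pulse_integration(self, cy5):
        # pulse-window integral of F(t) vs the closed form, 2-state scheme
        exc = Excitation(1e3)
        for w in [1e-6, 1e-5, 1e-4]:
            num = quad(
                lambda t: pulse_response(cy5, exc, np.array([t]))[0], 0.0, w,
                epsabs=1e-13, epsrel=1e-12, limit=200,
            )[0] / w
            assert mean_pulse_fluorescence(cy5, exc, w) == pytest.approx(
                num, abs=1e-8
            )

    def test_three_state_extension_consistent_with_quadrature(self, cy5):
        exc = Excitation(200e3)  # triplet branch active
        w = 2e-5
        num = quad(
            lambda t: pulse_response(cy5, exc, np.array([t]))[0], 0.0, w,
            epsabs=1e-12, epsrel=1e-10, limit=200,
        )[0] / w
        assert mean_pulse_fluorescence(cy5, exc, w) == pytest.approx(num, abs=1e-7)


class TestTrastCurve:
    def test_dark_free_curve_is_flat(self):
        trains = PulseTrain.series(default_width_grid())
        curve = trast_curve(dark_free_model(), Excitation(1e3), trains)
        assert np.allclose(curve.values, 1.0, atol=1e-12)

    def test_normalized_at_w0(self, cy5):
        trains = PulseTrain.series(default_width_grid())
        with pytest.warns(UserWarning):
            curve = trast_curve(cy5, Excitation(1e3), trains)
        assert curve.values[0] == pytest.approx(1.0, abs=1e-15)

    def test_matches_per_point_closed_form(self, cy5):
        exc = Excitation(1e3)
        widths = default_width_grid()
        trains = PulseTrain.series(widths)
        with pytest.warns(UserWarning):
            curve = trast_curve(cy5, exc, trains)
        means = np.asarray(mean_pulse_fluorescence(cy5, exc, widths))
        assert np.allclose(curve.values, means / means[0], rtol=1e-12)

    def test_monotone_non_increasing(self, cy5):
        trains = PulseTrain.series(default_width_grid())
        with pytest.warns(UserWarning):
            curve = trast_curve(cy5, Excitation(1e3), trains)
        assert np.all(np.diff(curve.values) <= 1e-15)

    def test_inconsistent_w0_rejected(self):
        trains = [PulseTrain(w=1e-6, w0=1e-7), PulseTrain(w=1e-5, w0=1e-8)]
        with pytest.raises(ValueError):
            trast_curve(dark_free_model(), Excitation(1e3), trains)

    def test_strictly_increasing_widths_enforced(self):
        with pytest.raises(ValueError):
            TrastCurve(widths=[1e-6, 1e-6], values=[1.0, 1.0])


class TestMixtureCurve:
    def trains(self):
        return PulseTrain.series(np.geomspace(1e-9, 1e-2, 40))

    def test_endpoints(self):
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        flat = mixture_trast_curve(p, 0.0, 2.7, self.trains())
        assert np.allclose(flat.values, 1.0, atol=1e-12)
        pure = mixture_trast_curve(p, 1.0, 2.7, self.trains())
        ref = trast_curve(p, None, self.trains())
        assert np.allclose(pure.values, ref.values, rtol=1e-12)

    def test_plateau_depression_brightness_weighted(self):
        # amplitude of the mixture = R*A / (R + (1-R)*Q) = 0.1216 for
        # R=0.5, Q=2.7, A=0.45
        p = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        curve = mixture_trast_curve(p, 0.5, 2.7, self.trains())
        depression = 1.0 - curve.values[-1]
        assert depression == pytest.approx(0.45 * 0.5 / (0.5 + 0.5 * 2.7), abs=1e-3)


class TestInterpulseRecovery:
    def test_fast_thermal_recovery_complete(self, cy5):
        model = IsomerizationModel(
            sigma_n=cy5.sigma_n, sigma_biso=cy5.sigma_biso, k_iso=cy5.k_iso,
            k_biso_th=1e9 - 1,  # below k10 bound, effectively instantaneous
        )
        train = PulseTrain(w=1e-5, n_pulses=20, duty_cycle=0.01)
        starts, limit = interpulse_recovery(model, Excitation(1e3), train)
        assert np.allclose(starts, 1.0, atol=1e-6)
        assert limit == pytest.approx(1.0, abs=1e-6)

    def test_unit_duty_cycle_no_recovery(self, cy5_flow):
        train = PulseTrain(w=1e-5, n_pulses=10, duty_cycle=1.0)
        starts, _ = interpulse_recovery(cy5_flow, Excitation(1e3), train)
        assert np.allclose(starts, 1.0)

    def test_gap_recovery_factor(self, cy5_flow):
        # over a gap of (1-eta) w / eta the dark pool shrinks by
        # exp(-k_biso_th * gap): 1-e^-0.158 = 0.146 recovery for w=1us
        for w, expected in [(100e-6, 1.0), (1e-6, 0.1465)]:
            gap = w * 0.99 / 0.01
            assert 1.0 - np.exp(-cy5_flow.k_biso_th * gap) == pytest.approx(
                expected, abs=2e-3
            )
        train = PulseTrain(w=1e-6, n_pulses=200, duty_cycle=0.01)
        starts, limit = interpulse_recovery(cy5_flow, Excitation(16e3), train)
        assert starts[0] == 1.0
        assert np.all(np.diff(starts) <= 0)  # carry-over builds up
        assert starts[-1] == pytest.approx(limit, rel=1e-6)
        assert limit < 0.9  # strong carry-over at this slow thermal rate

    def test_recursion_matches_brute_force(self, cy5_flow):
        exc = Excitation(16e3)
        from trastkit.fcs import dark_terms_from_model

        a, tau = dark_terms_from_model(cy5_flow, exc)
        train = PulseTrain(w=2e-6, n_pulses=30, duty_cycle=0.01)
        gap = train.w * (1 - train.duty_cycle) / train.duty_cycle
        n, seq = 1.0, []
        for _ in range(train.n_pulses):
            seq.append(n)
            n_end = (1 - a) + (n - (1 - a)) * np.exp(-train.w / tau)
            n = 1.0 - (1.0 - n_end) * np.exp(-cy5_flow.k_biso_th * gap)
        starts, _ = interpulse_recovery(cy5_flow, exc, train)
        assert np.allclose(starts, seq, rtol=1e-12)


class TestFitting:
    def test_noiseless_round_trip_exact(self):
        truth = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        trains = PulseTrain.series(default_width_grid())
        curve = trast_curve(truth, None, trains)
        res = MonoexpTrastModel(curve).fit()
        assert res.success
        assert res.params["a_trast"] == pytest.approx(0.45, abs=1e-6)
        assert res.params["tau_trast"] == pytest.approx(12.4e-6, rel=1e-6)

    def test_uncertainties_reported(self):
        truth = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        curve, _ = gen_trast_curve(truth, photon_budget=1e6, seed=7)
        res = MonoexpTrastModel(curve).fit()
        assert res.stderr["tau_trast"] is not None
        assert res.stderr["tau_trast"] > 0
        assert "tau_trast" in res.summary()

    def test_noisy_recovery_multiplicative(self, rng):
        # 1% multiplicative noise, 30 widths: parameters back within 5%
        truth = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        trains = PulseTrain.series(default_width_grid())
        clean = trast_curve(truth, None, trains)
        a_est, tau_est = [], []
        for _ in range(20):
            noisy = TrastCurve(
                widths=clean.widths,
                values=clean.values * (1 + 0.01 * rng.standard_normal(30)),
                w0=clean.w0,
            )
            res = MonoexpTrastModel(noisy).fit()
            a_est.append(res.params["a_trast"])
            tau_est.append(res.params["tau_trast"])
        assert np.mean(a_est) == pytest.approx(0.45, rel=0.05)
        assert np.mean(tau_est) == pytest.approx(12.4e-6, rel=0.05)

    def test_mixture_series_recovers_q(self, rng):
        truth = MonoexpTrastParams(a_trast=0.45, tau_trast=12.4e-6)
        trains = PulseTrain.series(default_width_grid())
        r_values = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        curves = []
        for r in r_values:
            clean = mixture_trast_curve(truth, r, 2.7, trains)
            curves.append(
                TrastCurve(
                    widths=clean.widths,
                    values=clean.values * (1 + 0.005 * rng.standard_normal(30)),
                    w0=clean.w0,
                )
            )
        res = MixtureTrastModel(curves, r_values, truth).fit()
        assert res.success
        assert res.params["q_ratio"] == pytest.approx(2.7, rel=0.10)

    def test_functional_wrapper(self):
        truth = MonoexpTrastParams(a_trast=0.3, tau_trast=5e-6)
        curve = trast_curve(truth, None, PulseTrain.series(default_width_grid()))
        res = fit_trast(curve, "monoexp")
        assert res.params["a_trast"] == pytest.approx(0.3, abs=1e-6)
        with pytest.raises(ValueError):
            fit_trast(curve, "bogus")

    def test_too_few_points_rejected(self):
        curve = TrastCurve(widths=[1e-7, 1e-6, 1e-5], values=[1.0, 0.9, 0.8])
        with pytest.raises(ValueError):
            MonoexpTrastModel(curve)
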