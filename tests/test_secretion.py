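"""C-peptide secretion model: kinetics, simulation oracles, fitting."""

import numpy as np
import pytest

from oralmm.core import basal_value
from oralmm.engine import SignalInterpolant, integrate
from oralmm.secretion import (
    SecretionParams,
    fit_secretion,
    isr_summary,
    kinetics_from_biexp,
    phi_total,
    simulate_secretion,
    vancauter_kinetics,
)

TIMES = np.array([-10., -1., 10., 20., 30., 45., 60., 90., 120., 150., 180.])
GLUCOSE = np.array([5.2, 5.2, 6.5, 8.0, 9.5, 10.0, 9.0, 7.5, 6.2, 5.6, 5.3])


@pytest.fixture
def kin():
    return kinetics_from_biexp(0.76, 4.95, 29.2, vc=4.2)


@pytest.fixture
def glucose():
    return SignalInterpolant(TIMES, GLUCOSE)


class TestKinetics:
    def test_equal_half_lives_collapse_to_one_compartment(self):
        kin = kinetics_from_biexp(0.5, 10.0, 10.0, vc=4.0)
        assert kin.k21 == pytest.approx(0.0, abs=1e-12)

    def test_fraction_one_limit(self):
        a, b = np.log(2) / 4.95, np.log(2) / 29.2
        kin = kinetics_from_biexp(1.0 - 1e-12, 4.95, 29.2, vc=4.0)
        assert kin.k12 == pytest.approx(b, rel=1e-9)
        assert kin.k01 == pytest.approx(a, rel=1e-9)

    @pytest.mark.parametrize("F,tf,ts", [(0.76, 4.95, 29.2), (0.6, 3.0, 40.0),
                                         (0.9, 5.0, 20.0)])
    def test_impulse_response_matches_biexponential(self, F, tf, ts):
        kin = kinetics_from_biexp(F, tf, ts, vc=4.0)
        a, b = np.log(2) / tf, np.log(2) / ts
        A = kin.matrix
        t = np.linspace(0, 150, 151)
        out = integrate(lambda tt, x: A @ x, [1.0, 0.0], t)
        closed = F * np.exp(-a * t) + (1 - F) * np.exp(-b * t)
        assert np.max(np.abs(out[:, 0] - closed)) < 1e-6

    def test_population_kinetics_need_anthropometry(self, tiny_subject):
        kin = vancauter_kinetics(tiny_subject, diabetic=False)
        assert kin.vc > 2.0  # litres, scales with body surface area
        tiny_subject.height = np.nan
        with pytest.raises(ValueError, match="height"):
            vancauter_kinetics(tiny_subject, diabetic=False)


class TestSimulate:
    def test_null_secretion_stays_at_basal(self, kin, glucose):
        p = SecretionParams(phi_d=0.0, phi_s=0.0, tau=10.0, h=5.2)
        sim = simulate_secretion(kin, p, glucose, 5.2, 300.0,
                                 np.arange(0.0, 181.0, 1.0))
        assert np.allclose(sim["cp"], 300.0, atol=1e-9)
        assert np.allclose(sim["sr"], 0.0, atol=1e-12)

    def test_glucose_step_first_order_response(self, kin):
        """With phi_d=0 and a glucose step of height dG above threshold,
        sr_s follows phi_s * dG * (1 - e^(-t/tau))."""
        step = SignalInterpolant([-10.0, -0.001, 0.0, 180.0],
                                 [5.0, 5.0, 9.0, 9.0])
        p = SecretionParams(phi_d=0.0, phi_s=20.0, tau=15.0, h=5.0)
        t = np.arange(0.0, 181.0, 1.0)
        sim = simulate_secretion(kin, p, step, 5.0, 300.0, t)
        closed = 20.0 * 4.0 * (1.0 - np.exp(-t / 15.0))
        assert np.max(np.abs(sim["sr_s"] - closed)) < 1e-6

    def test_trajectory_matches_independent_integrator(self, kin, glucose):
        p = SecretionParams(phi_d=400.0, phi_s=30.0, tau=12.0, h=5.2)
        t = np.concatenate([[0.0], TIMES[TIMES > 0]])
        sim = simulate_secretion(kin, p, glucose, 5.2, 300.0, t)

        def rhs(tt, x):
            cp1, cp2, srs = x
            srd = p.phi_d * max(glucose.derivative(tt + 1e-9), 0.0)
            return [
                -(kin.k01 + kin.k21) * cp1 + kin.k12 * cp2 + srd + srs,
                kin.k21 * cp1 - kin.k12 * cp2,
                (-srs + p.phi_s * max(glucose(tt) - p.h, 0.0)) / p.tau,
            ]

        ref = integrate(rhs, [0, 0, 0], t, discontinuities=TIMES,
                        rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(sim["cp"] - (ref[:, 0] + 300.0))) < 1e-6

    def test_mass_decays_without_secretion(self, kin, glucose):
        """Above-basal C-peptide injected at t=0 washes out when sr == 0."""
        p = SecretionParams(phi_d=0.0, phi_s=0.0, tau=10.0, h=99.0)
        A = kin.matrix
        t = np.linspace(0, 600, 11)
        out = integrate(lambda tt, x: A @ x, [50.0, 20.0], t)
        assert np.all(np.diff(np.abs(out.sum(axis=1))) <= 1e-9)
        assert abs(out[-1]).max() < 1e-3


class TestPhiTotal:
    def test_square_excursion_tau_zero_limit(self, kin):
        """With h=gb, phi_d=0 and a long square glucose excursion,
        phi_total approaches phi_s as tau -> 0."""
        sq = SignalInterpolant([-10.0, -0.001, 0.0, 2000.0],
                               [5.0, 5.0, 8.0, 8.0])
        p = SecretionParams(phi_d=0.0, phi_s=25.0, tau=0.05, h=5.0)
        val = phi_total(p, sq, 5.0, kin, t_end=2000.0)
        assert val == pytest.approx(25.0, rel=1e-3)

    def test_dynamic_component_analytic_on_triangle(self, kin):
        """For a single triangular excursion the dynamic part contributes
        exactly phi_d * dG_rise / integral(G - gb)."""
        tri = SignalInterpolant([-10.0, 0.0, 60.0, 120.0, 180.0],
                                [5.0, 5.0, 9.0, 5.0, 5.0])
        pd_ = SecretionParams(phi_d=300.0, phi_s=10.0, tau=8.0, h=5.0)
        ps = SecretionParams(phi_d=0.0, phi_s=10.0, tau=8.0, h=5.0)
        excursion = 0.5 * 120.0 * 4.0  # triangle area of (G - gb)
        got = (phi_total(pd_, tri, 5.0, kin, 180.0)
               - phi_total(ps, tri, 5.0, kin, 180.0))
        assert got == pytest.approx(300.0 * 4.0 / excursion, rel=1e-3)

    def test_linear_in_secretion_parameters(self, kin, glucose):
        p1 = SecretionParams(phi_d=200.0, phi_s=15.0, tau=10.0, h=5.2)
        p2 = SecretionParams(phi_d=400.0, phi_s=30.0, tau=10.0, h=5.2)
        v1 = phi_total(p1, glucose, 5.2, kin)
        v2 = phi_total(p2, glucose, 5.2, kin)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-9)

    def test_monotone_in_phi_s_and_phi_d(self, kin, glucose):
        base = SecretionParams(phi_d=200.0, phi_s=15.0, tau=10.0, h=5.2)
        up_s = SecretionParams(phi_d=200.0, phi_s=20.0, tau=10.0, h=5.2)
        up_d = SecretionParams(phi_d=300.0, phi_s=15.0, tau=10.0, h=5.2)
        v0 = phi_total(base, glucose, 5.2, kin)
        assert phi_total(up_s, glucose, 5.2, kin) >= v0
        assert phi_total(up_d, glucose, 5.2, kin) >= v0


class TestIsrSummary:
    def test_dynamic_peak_at_max_slope(self, kin, glucose):
        p = SecretionParams(phi_d=400.0, phi_s=0.0, tau=10.0, h=5.2)
        t = np.arange(0.0, 181.0, 1.0)
        sim = simulate_secretion(kin, p, glucose, 5.2, 300.0, t)
        peaks = isr_summary(t, sim["sr_d"], sim["sr_s"])
        slopes = np.diff(GLUCOSE) / np.diff(TIMES)
        t_max_slope = TIMES[np.argmax(slopes)]
        assert peaks.t_max_dynamic == pytest.approx(max(t_max_slope, 0.0), abs=1.0)

    def test_sustained_step_static_peak_at_window_end(self, kin):
        step = SignalInterpolant([-10.0, -0.001, 0.0, 180.0],
                                 [5.0, 5.0, 9.0, 9.0])
        p = SecretionParams(phi_d=0.0, phi_s=20.0, tau=15.0, h=5.0)
        t = np.arange(0.0, 181.0, 1.0)
        sim = simulate_secretion(kin, p, step, 5.0, 300.0, t)
        peaks = isr_summary(t, sim["sr_d"], sim["sr_s"])
        assert peaks.t_max_static == pytest.approx(180.0)

    def test_biphasic_profile_matches_grid_scan(self, kin, glucose):
        p = SecretionParams(phi_d=400.0, phi_s=30.0, tau=12.0, h=5.2)
        t = np.arange(0.0, 180.5, 1.0)
        sim = simulate_secretion(kin, p, glucose, 5.2, 300.0, t)
        peaks = isr_summary(t, sim["sr_d"], sim["sr_s"])
        # brute-force scan oracle
        k = int(np.argmax(sim["sr_s"]))
        assert peaks.isr_max_static == pytest.approx(sim["sr_s"][k])
        assert peaks.t_max_static == pytest.approx(t[k])

    def test_all_zero_component_reported_missing(self):
        t = np.arange(0.0, 10.0)
        peaks = isr_summary(t, np.zeros(10), np.ones(10))
        assert peaks.isr_max_dynamic == 0.0
        assert np.isnan(peaks.t_max_dynamic)


class TestFit:
    def test_noise_free_recovery(self, noisefree_cohort_small):
        subject, series, truth = noisefree_cohort_small[0]
        kin = vancauter_kinetics(subject, diabetic=False)
        params, fit = fit_secretion(series, kin, n_starts=3)
        assert fit.converged
        assert params.phi_d == pytest.approx(truth["phi_d"], rel=0.01)
        assert params.phi_s == pytest.approx(truth["phi_s"], rel=0.01)
        assert params.tau == pytest.approx(truth["tau"], rel=0.01)

    def test_flat_cpeptide_flagged_low_identifiability(self, tiny_series,
                                                       tiny_subject):
        tiny_series.cpeptide[:] = 300.0
        kin = vancauter_kinetics(tiny_subject, diabetic=False)
        params, fit = fit_secretion(tiny_series, kin, n_starts=2)
        assert params.phi_d <= 1e-6 and params.phi_s <= 1e-6
        assert not fit.converged
        assert "low-identifiability" in fit.message

    def test_phi_b_derived_from_basal_closure(self, noisefree_cohort_small):
        subject, series, truth = noisefree_cohort_small[0]
        kin = vancauter_kinetics(subject, diabetic=False)
        params, _ = fit_secretion(series, kin, n_starts=1)
        gb = basal_value(series, "glucose")
        cpb = basal_value(series, "cpeptide")
        assert params.phi_b == pytest.approx(kin.k01 * cpb / gb, rel=1e-12)
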