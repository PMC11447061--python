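"""ODE integration, forcing interpolants and weighted NLS with multi-start."""

import numpy as np
import pytest

from oralmm.engine import SignalInterpolant, integrate, wnls_fit
from oralmm.secretion import kinetics_from_biexp


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        out = integrate(lambda t, x: -0.1 * x, [1.0], np.array([0.0, 10.0]))
        assert out[-1, 0] == pytest.approx(np.exp(-1.0), abs=1e-8)

    def test_zero_rhs_constant_trajectory(self):
        out = integrate(lambda t, x: 0.0 * x, [2.5], np.array([0.0, 50.0, 100.0]))
        assert np.allclose(out, 2.5)

    def test_two_compartment_impulse_vs_biexponential(self):
        """Impulse response of the population C-peptide system equals
        F e^{-at} + (1-F) e^{-bt} by construction of the rate constants."""
        F, t_fast, t_slow = 0.76, 4.95, 29.2
        kin = kinetics_from_biexp(F, t_fast, t_slow, vc=4.0)
        a, b = np.log(2) / t_fast, np.log(2) / t_slow
        A = np.array([[-(kin.k01 + kin.k21), kin.k12], [kin.k21, -kin.k12]])
        t = np.linspace(0.0, 120.0, 121)
        out = integrate(lambda tt, x: A @ x, [1.0, 0.0], t)
        closed = F * np.exp(-a * t) + (1 - F) * np.exp(-b * t)
        assert np.max(np.abs(out[:, 0] - closed)) < 1e-6

    def test_solver_failure_carries_context(self):
        from oralmm.engine import SolverError

        with pytest.raises((SolverError, ValueError)):
            integrate(lambda t, x: x ** 3, [10.0], np.array([0.0, 100.0]))


class TestSignalInterpolant:
    def test_knot_exactness_and_hold(self):
        f = SignalInterpolant([0.0, 10.0, 30.0], [1.0, 3.0, 2.0])
        assert f(10.0) == pytest.approx(3.0)
        assert f(-5.0) == pytest.approx(1.0)  # held outside the knots
        assert f(40.0) == pytest.approx(2.0)

    def test_right_sided_derivative_at_knots(self):
        f = SignalInterpolant([0.0, 10.0, 30.0], [0.0, 10.0, 0.0])
        assert f.derivative(10.0) == pytest.approx(-0.5)
        assert f.derivative(5.0) == pytest.approx(1.0)

    def test_level_crossings_exact(self):
        f = SignalInterpolant([0.0, 10.0, 20.0], [0.0, 10.0, 0.0])
        assert np.allclose(f.crossings(5.0), [5.0, 15.0])


class TestWnlsFit:
    def test_linear_model_exact_recovery(self):
        t = np.linspace(1.0, 10.0, 10)
        data = 2.5 * t
        fit = wnls_fit(lambda th: th[0] * t, data, np.ones_like(t),
                       {"theta": (0.1, 100.0)}, transforms={"theta": "log"},
                       n_starts=3, seed=1)
        assert fit.estimates["theta"] == pytest.approx(2.5, abs=1e-10)
        assert fit.objective == pytest.approx(0.0, abs=1e-16)

    def test_exponential_decay_simulate_then_fit(self):
        t = np.linspace(0.0, 20.0, 15)
        k_true = 0.31
        data = np.exp(-k_true * t)
        fit = wnls_fit(lambda th: np.exp(-th[0] * t), data, np.ones_like(t),
                       {"k": (0.01, 5.0)}, transforms={"k": "log"},
                       n_starts=5, seed=2)
        assert fit.estimates["k"] == pytest.approx(k_true, rel=1e-6)

    def test_same_seed_bit_identical(self):
        t = np.linspace(0.0, 5.0, 12)
        rng = np.random.default_rng(3)
        data = np.exp(-0.5 * t) + 0.01 * rng.standard_normal(t.size)

        def run():
            return wnls_fit(lambda th: np.exp(-th[0] * t), data,
                            np.ones_like(t), {"k": (0.01, 5.0)},
                            transforms={"k": "log"}, n_starts=4, seed=7)

        f1, f2 = run(), run()
        assert f1.estimates["k"] == f2.estimates["k"]  # bit-identical
        assert f1.objective == f2.objective
        assert np.array_equal(f1.residuals, f2.residuals)

    def test_optimum_beats_every_start(self):
        t = np.linspace(0.0, 5.0, 12)
        rng = np.random.default_rng(4)
        data = np.exp(-0.7 * t) + 0.05 * rng.standard_normal(t.size)
        fit = wnls_fit(lambda th: np.exp(-th[0] * t), data, np.ones_like(t),
                       {"k": (0.01, 5.0)}, transforms={"k": "log"},
                       n_starts=6, seed=5)
        assert np.all(fit.objective <= fit.start_initial_objectives + 1e-12)

    def test_doubling_weights_doubles_objective_same_argmin(self):
        t = np.linspace(0.0, 5.0, 12)
        rng = np.random.default_rng(6)
        data = np.exp(-0.4 * t) + 0.02 * rng.standard_normal(t.size)
        f1 = wnls_fit(lambda th: np.exp(-th[0] * t), data, np.ones_like(t),
                      {"k": (0.01, 5.0)}, transforms={"k": "log"},
                      n_starts=3, seed=8)
        f2 = wnls_fit(lambda th: np.exp(-th[0] * t), data, 2 * np.ones_like(t),
                      {"k": (0.01, 5.0)}, transforms={"k": "log"},
                      n_starts=3, seed=8)
        assert f2.estimates["k"] == pytest.approx(f1.estimates["k"], rel=1e-8)
        assert f2.objective == pytest.approx(2 * f1.objective, rel=1e-8)

    def test_fractional_sd_present_for_every_parameter(self):
        t = np.linspace(0.0, 5.0, 20)
        rng = np.random.default_rng(9)
        data = 3.0 * np.exp(-0.4 * t) + 0.03 * rng.standard_normal(t.size)
        fit = wnls_fit(lambda th: th[1] * np.exp(-th[0] * t), data,
                       np.ones_like(t), {"k": (0.01, 5.0), "A": (0.1, 10.0)},
                       transforms={"k": "log", "A": "log"}, n_starts=3, seed=10)
        assert set(fit.fractional_sd) == {"k", "A"}
        assert all(np.isfinite(v) for v in fit.fractional_sd.values())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wnls_fit(lambda th: th, np.ones(3), np.zeros(3),
                     {"a": (0.0, 1.0)})
        with pytest.raises(ValueError):
            wnls_fit(lambda th: th, np.ones(3), np.ones(3),
                     {"a": (0.0, 1.0)}, n_starts=0)
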