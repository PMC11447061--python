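"""Group statistics: disposition index, hyperbola, robust models, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from oralmm.stats import (
    association_models,
    disposition_index,
    fit_hyperbola,
    group_compare,
    spearman,
    trend_test,
)


class TestDispositionIndex:
    def test_unit_bookkeeping_example(self):
        # 50e-9 min^-1 times 10e-4 -> 500 on the 1e-13 scale
        assert disposition_index(50.0, 10.0) == pytest.approx(500.0)

    def test_zero_sensitivity(self):
        assert disposition_index(42.0, 0.0) == 0.0

    def test_elementwise_product_oracle(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(1, 100, 50)
        si = rng.uniform(0.1, 20, 50)
        assert np.allclose(disposition_index(phi, si), phi * si)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            disposition_index(-1.0, 2.0)


class TestHyperbola:
    def test_exact_hyperbola(self):
        si = np.array([1.0, 2.0, 4.0, 10.0])
        assert fit_hyperbola(si, 1000.0 / si) == pytest.approx(1000.0)

    def test_single_point_forced(self):
        assert fit_hyperbola([2.0], [5.0]) == pytest.approx(10.0)

    def test_closed_form_equals_numeric_minimiser(self):
        rng = np.random.default_rng(1)
        si = rng.uniform(0.5, 15, 30)
        phi = 800.0 / si * np.exp(0.2 * rng.standard_normal(30))
        beta_closed = fit_hyperbola(si, phi)
        oracle = np.sum(phi / si) / np.sum(1.0 / si ** 2)
        assert beta_closed == pytest.approx(oracle, abs=1e-10)
        num = minimize_scalar(lambda b: np.sum((phi - b / si) ** 2),
                              bounds=(1.0, 1e5), method="bounded",
                              options={"xatol": 1e-10})
        assert beta_closed == pytest.approx(num.x, rel=1e-6)

    def test_nonpositive_si_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperbola([1.0, -2.0], [3.0, 4.0])


def make_groups(rng, means, sizes, sd=1.0):
    vals, labs = [], []
    for m, n, lab in zip(means, sizes, ("NGT", "EGI", "IGT", "CFRD")):
        vals.append(rng.normal(m, sd, n))
        labs += [lab] * n
    return np.concatenate(vals), np.array(labs)


class TestGroupCompare:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(10.0) / 3 + 5.0, 4)
        labs = np.repeat(["NGT", "EGI", "IGT", "CFRD"], 10)
        cmp = group_compare(vals, labs)
        assert np.allclose(cmp.pairwise["estimate"], 0.0, atol=1e-12)
        assert np.all(cmp.pairwise["p"] > 0.99)
        assert np.allclose(cmp.table["mean"], vals.mean())

    def test_location_shift_recovered(self):
        rng = np.random.default_rng(2)
        vals, labs = make_groups(rng, [10.0, 10.0, 10.0, 13.0],
                                 [13, 20, 10, 18], sd=1e-4)
        cmp = group_compare(vals, labs)
        row = cmp.pairwise.query("group_a=='NGT' and group_b=='CFRD'")
        assert row["estimate"].iloc[0] == pytest.approx(-3.0, abs=1e-3)
        assert row["p"].iloc[0] < 1e-10

    def test_log_transform_backmaps_to_geometric_means(self):
        rng = np.random.default_rng(3)
        vals, labs = make_groups(rng, [2.0, 1.5, 1.0, 0.5], [13, 20, 10, 18])
        vals = np.exp(vals)
        cmp = group_compare(vals, labs, transform="log")
        for _, r in cmp.table.iterrows():
            geo = np.exp(np.mean(np.log(vals[labs == r["group"]])))
            assert r["mean"] == pytest.approx(geo, rel=1e-9)
            assert 0 < r["ci_lo"] < r["mean"] < r["ci_hi"]

    def test_small_group_excluded(self):
        vals = np.concatenate([np.arange(10.0), [5.0]])
        labs = np.array(["NGT"] * 5 + ["EGI"] * 5 + ["IGT"])
        cmp = group_compare(vals, labs)
        assert set(cmp.table["group"]) == {"NGT", "EGI"}


class TestTrendTest:
    def test_perfect_trend(self):
        codes = np.repeat([0, 1, 2, 3], 8)
        rng = np.random.default_rng(4)
        slope, p = trend_test(codes + 1e-6 * rng.standard_normal(32), codes)
        assert slope == pytest.approx(1.0, abs=1e-4)
        assert p < 1e-12

    def test_constant_outcome_p_one(self):
        codes = np.repeat([0, 1, 2, 3], 5)
        slope, p = trend_test(np.full(20, 7.0), codes)
        assert p == 1.0

    def test_logistic_positive_slope_for_rising_prevalence(self):
        rng = np.random.default_rng(5)
        codes = np.repeat([0, 1, 2, 3], 30)
        prev = np.array([0.1, 0.3, 0.5, 0.8])[codes]
        y = (rng.random(codes.size) < prev).astype(float)
        slope, p = trend_test(y, codes, family="logistic")
        assert slope > 0

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            trend_test([1.0, 2.0], [0, 1])


class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x, np.exp(y))  # strictly increasing transform
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)

    def test_antitone(self):
        x = np.arange(10.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 5.0, 6.0])

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(v.size)
            i = 0
            sv = v[order]
            while i < v.size:
                j = i
                while j < v.size and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))


class TestAssociationModels:
    def test_constant_adjustment_is_noop(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.standard_normal(n)
        y = 0.3 * x + 0.1 * rng.standard_normal(n)
        pred = pd.DataFrame({"x": x})
        cov = pd.DataFrame({"bmi": np.full(n, 22.0)})
        est = association_models(pd.Series(y), pred, cov, "minimal")[0]
        import statsmodels.api as sm

        ref = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
        assert est.slope == pytest.approx(ref.params[1], abs=1e-10)

    def test_simulated_effect_size_recovered(self):
        """Clearance rising 0.004 min^-1 per unit decline in phi_total is
        recovered from a BMI-confounded simulation at large n."""
        rng = np.random.default_rng(8)
        n = 4000
        phi_total = rng.uniform(5, 80, n)
        bmi = rng.normal(22, 3, n)
        clearance = 0.5 - 0.004 * phi_total + 0.002 * (bmi - 22) \
            + 0.01 * rng.standard_normal(n)
        pred = pd.DataFrame({"phi_total": phi_total})
        cov = pd.DataFrame({"bmi": bmi})
        est = association_models(pd.Series(clearance), pred, cov, "minimal")[0]
        assert est.slope == pytest.approx(-0.004, abs=2e-4)
        assert est.ci_lo < -0.004 < est.ci_hi

    def test_predictor_dropped_from_own_adjustment(self):
        rng = np.random.default_rng(9)
        n = 50
        bmi = rng.normal(22, 3, n)
        y = 0.02 * bmi + 0.01 * rng.standard_normal(n)
        pred = pd.DataFrame({"bmi": bmi})
        cov = pd.DataFrame({"bmi": bmi})
        ests = association_models(pd.Series(y), pred, cov, "minimal")
        assert len(ests) == 1  # model kept, self-adjustment dropped
        assert np.isfinite(ests[0].slope)

    def test_interval_contains_slope(self):
        rng = np.random.default_rng(10)
        n = 40
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        est = association_models(
            pd.Series(y), pd.DataFrame({"x": x}),
            pd.DataFrame({"bmi": rng.normal(22, 2, n)}), "minimal")[0]
        assert est.ci_lo <= est.slope <= est.ci_hi
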