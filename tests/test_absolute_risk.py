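import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrisk.absolute_risk import (
    absolute_risk_curve,
    calibrate_baseline,
    monte_carlo_ci,
    plugin_curves,
    population_frequencies,
    weight_ors,
)
from polyrisk.association import ORTable
from polyrisk.io_cohort import RateSchedule


def schedule(incidence, mortality, start=40):
    incidence = np.asarray(incidence, dtype=float)
    mortality = np.asarray(mortality, dtype=float)
    ages = np.arange(start, start + len(incidence))
    return RateSchedule(ages, incidence, mortality)


def freqs_of(d, prevalence=0.167):
    cats = list(d)
    p = pd.Series(d, dtype=float)
    return population_frequencies(p / p.sum(), p / p.sum(), prevalence)


def ortable(beta: dict, cov: np.ndarray, reference="intermediate_noncarrier") -> ORTable:
    cats = list(beta)
    b = pd.Series(beta, dtype=float)
    return ORTable(
        outcome="overall", categories=[reference] + cats, reference=reference,
        or_=np.exp(b), ci_lo=np.exp(b), ci_hi=np.exp(b), p=b * 0,
        beta=b, cov=pd.DataFrame(cov, index=cats, columns=cats),
        counts=pd.DataFrame(1, index=[reference] + cats, columns=["n_cases", "n_controls"]),
    )


class TestWeightOrs:
    def test_equal_ors_unchanged(self):
        assert weight_ors(2.5, 2.5, 0.37).or_weighted == pytest.approx(2.5)

    def test_hand_arithmetic(self):
        # 0.37*2.0 + 0.63*1.0 = 1.37
        assert weight_ors(2.0, 1.0, 0.37).or_weighted == pytest.approx(1.37)

    def test_weight_one_returns_aggressive(self):
        assert weight_ors(3.7, 1.2, 1.0).or_weighted == pytest.approx(3.7)

    def test_log_scale_alternative_is_geometric(self):
        w = weight_ors(4.0, 1.0, 0.5, log_scale=True)
        assert w.or_weighted == pytest.approx(2.0)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            weight_ors(0.0, 1.0, 0.37)

    def test_mixture_between_inputs(self):
        w = weight_ors(5.0, 1.5, 0.37)
        assert 1.5 <= w.or_weighted <= 5.0


class TestPopulationFrequencies:
    def test_equal_case_control_mixture_is_identity(self):
        f = pd.Series({"a": 0.4, "b": 0.6})
        res = population_frequencies(f, f, 0.167)
        assert np.allclose(res.p, f)

    def test_prevalence_weighted_mixture_arithmetic(self):
        # 0.167*0.033 + 0.833*0.006 = 0.010509
        f_case = pd.Series({"g": 0.033, "rest": 0.967})
        f_ctrl = pd.Series({"g": 0.006, "rest": 0.994})
        res = population_frequencies(f_case, f_ctrl, 0.167)
        assert res.p["g"] == pytest.approx(0.167 * 0.033 + 0.833 * 0.006, abs=1e-9)

    def test_frequencies_sum_to_one(self):
        f_case = pd.Series({"a": 0.2, "b": 0.8})
        f_ctrl = pd.Series({"a": 0.5, "b": 0.5})
        res = population_frequencies(f_case, f_ctrl, 0.3)
        assert res.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_prevalence_bounds_enforced(self):
        f = pd.Series({"a": 1.0})
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                population_frequencies(f, f, bad)


class TestCalibrateBaseline:
    def test_single_reference_category_identity(self):
        sched = schedule([0.002] * 5, [0.0] * 5)
        freqs = freqs_of({"only": 1.0})
        lam0 = calibrate_baseline(sched, freqs, pd.Series({"only": 1.0}))
        assert np.allclose(lam0, sched.incidence)

    def test_two_category_hand_example(self):
        # p = (.5, .5), r = (1, 3), lambda_pop = 0.002 -> lambda0 = 0.001
        sched = schedule([0.002] * 3, [0.0] * 3)
        freqs = freqs_of({"ref": 0.5, "hi": 0.5})
        lam0 = calibrate_baseline(sched, freqs, pd.Series({"ref": 1.0, "hi": 3.0}))
        assert np.allclose(lam0, 0.001)

    def test_uniform_scaling(self):
        sched = schedule([0.004] * 3, [0.0] * 3)
        freqs = freqs_of({"a": 0.3, "b": 0.7})
        lam0 = calibrate_baseline(sched, freqs, pd.Series({"a": 2.0, "b": 2.0}))
        assert np.allclose(lam0, sched.incidence / 2.0)

    @given(
        seed=st.integers(0, 10_000),
        k=st.integers(1, 6),
    )
    @settings(max_examples=60, deadline=None)
    def test_calibration_identity_exact_at_every_age(self, seed, k):
        rng = np.random.default_rng(seed)
        n_ages = int(rng.integers(3, 40))
        sched = schedule(rng.uniform(0, 0.05, n_ages), rng.uniform(0, 0.05, n_ages))
        p = rng.dirichlet(np.ones(k))
        r = rng.uniform(0.2, 8.0, k)
        cats = [f"c{j}" for j in range(k)]
        freqs = freqs_of(dict(zip(cats, p)))
        lam0 = calibrate_baseline(sched, freqs, pd.Series(r, index=cats))
        recon = lam0 * float((freqs.p * pd.Series(r, index=cats)).sum())
        np.testing.assert_allclose(recon, sched.incidence, rtol=1e-15)


class TestAbsoluteRiskCurve:
    def test_closed_form_geometric_limit(self):
        # constant hazard 0.01, no competing mortality, 10 years
        sched = schedule([0.01] * 10, [0.0] * 10)
        curve = absolute_risk_curve(np.full(10, 0.01), 1.0, sched)
        assert curve.ar[-1] == pytest.approx(1 - 0.99**10, rel=1e-12)
        # matches discrete cumulative incidence at every age
        expected = 1 - np.cumprod(1 - np.full(10, 0.01))
        np.testing.assert_allclose(curve.ar, expected, rtol=1e-12)

    def test_zero_hazard_zero_risk(self):
        sched = schedule([0.0] * 5, [0.01] * 5)
        curve = absolute_risk_curve(np.zeros(5), 1.0, sched)
        assert np.all(curve.ar == 0)

    def test_zero_relative_risk_zero_risk(self):
        sched = schedule([0.01] * 5, [0.01] * 5)
        curve = absolute_risk_curve(sched.incidence, 0.0, sched)
        assert np.all(curve.ar == 0)

    def test_nondecreasing_in_age_and_increasing_in_rr(self):
        rng = np.random.default_rng(3)
        sched = schedule(rng.uniform(0.001, 0.03, 30), rng.uniform(0.001, 0.05, 30))
        lo = absolute_risk_curve(sched.incidence, 1.0, sched)
        hi = absolute_risk_curve(sched.incidence, 2.5, sched)
        assert np.all(np.diff(lo.ar) >= 0)
        assert np.all(hi.ar >= lo.ar)
        assert hi.ar[-1] > lo.ar[-1]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_more_competing_mortality_never_increases_risk(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        inc = rng.uniform(0, 0.05, n)
        mu = rng.uniform(0, 0.2, n)
        bump = rng.uniform(0, 0.2, n)
        base = absolute_risk_curve(inc, 1.3, schedule(inc, mu))
        more = absolute_risk_curve(inc, 1.3, schedule(inc, np.minimum(mu + bump, 0.99)))
        assert np.all(more.ar <= base.ar + 1e-15)

    def test_survival_floor_clamps_extreme_hazard(self):
        sched = schedule([0.5] * 5, [0.6] * 5)
        curve = absolute_risk_curve(sched.incidence, 2.0, sched)
        assert np.all(curve.ar <= 1.0)
        assert np.all(np.diff(curve.ar) >= 0)


class TestMonteCarlo:
    def _inputs(self):
        rng = np.random.default_rng(0)
        sched = schedule(rng.uniform(0.001, 0.01, 20), rng.uniform(0.005, 0.02, 20))
        beta = {"low_noncarrier": np.log(0.6), "high_noncarrier": np.log(3.0),
                "high_carrier": np.log(12.0)}
        freqs = freqs_of({"intermediate_noncarrier": 0.5, "low_noncarrier": 0.3,
                          "high_noncarrier": 0.19, "high_carrier": 0.01})
        return sched, beta, freqs

    def test_zero_covariance_degenerates_to_plugin_curve(self):
        sched, beta, freqs = self._inputs()
        tab = ortable(beta, np.zeros((3, 3)))
        curves = monte_carlo_ci(tab, freqs, sched, n_iter=50, seed=1)
        plug = plugin_curves(tab, freqs, sched)
        for cat in curves:
            np.testing.assert_allclose(curves[cat].ar, plug[cat].ar, rtol=1e-12)
            np.testing.assert_allclose(curves[cat].ci_lo, curves[cat].ci_hi, atol=1e-15)

    def test_fixed_seed_bit_identical(self):
        sched, beta, freqs = self._inputs()
        tab = ortable(beta, np.diag([0.04, 0.01, 0.2]))
        c1 = monte_carlo_ci(tab, freqs, sched, n_iter=100, seed=42)
        c2 = monte_carlo_ci(tab, freqs, sched, n_iter=100, seed=42)
        for cat in c1:
            assert np.array_equal(c1[cat].ar, c2[cat].ar)
            assert np.array_equal(c1[cat].ci_lo, c2[cat].ci_lo)

    def test_ci_brackets_estimate_and_widens_with_variance(self):
        sched, beta, freqs = self._inputs()
        tab = ortable(beta, np.diag([0.04, 0.01, 0.2]))
        curves = monte_carlo_ci(tab, freqs, sched, n_iter=400, seed=5)
        c = curves["high_carrier"]
        assert np.all(c.ci_lo <= c.ar + 1e-12) and np.all(c.ar <= c.ci_hi + 1e-12)
        width_hc = c.ci_hi[-1] - c.ci_lo[-1]
        width_hn = curves["high_noncarrier"].ci_hi[-1] - curves["high_noncarrier"].ci_lo[-1]
        assert width_hc > width_hn  # larger coefficient variance -> wider band

    def test_mc_mean_converges(self):
        sched, beta, freqs = self._inputs()
        tab = ortable(beta, np.diag([0.04, 0.01, 0.2]))
        small = monte_carlo_ci(tab, freqs, sched, n_iter=400, seed=7)
        big = monte_carlo_ci(tab, freqs, sched, n_iter=4000, seed=8)
        # difference of means within 3 MC standard errors of the small run
        for cat in ("high_carrier", "high_noncarrier"):
            spread = (small[cat].ci_hi[-1] - small[cat].ci_lo[-1]) / (2 * 1.96)
            se = spread / np.sqrt(400)
            assert abs(small[cat].ar[-1] - big[cat].ar[-1]) < 3 * se + 1e-4

    def test_non_psd_covariance_rejected(self):
        sched, beta, freqs = self._inputs()
        bad = np.diag([0.1, 0.1, -0.5])
        tab = ortable(beta, bad)
        with pytest.raises(ValueError, match="positive semi-definite"):
            monte_carlo_ci(tab, freqs, sched, n_iter=10, seed=0)

    def test_population_average_close_to_population_curve(self):
        # static-frequency approximation: mixture of category curves tracks
        # the single-category population curve within ~2% relative error
        rng = np.random.default_rng(9)
        ages = 46
        inc = 0.0002 * 2 ** (np.arange(ages) / 10)
        mu = 0.003 * 2 ** (np.arange(ages) / 10)
        sched = schedule(inc, mu, start=40)
        beta = {"low": np.log(0.6), "high": np.log(3.0)}
        freqs = freqs_of({"intermediate": 0.34, "low": 0.33, "high": 0.33})
        tab = ortable(beta, np.zeros((2, 2)), reference="intermediate")
        curves = plugin_curves(tab, freqs, sched)
        mix = sum(freqs.p[c] * curves[c].ar for c in curves)
        pop = absolute_risk_curve(inc, 1.0, sched).ar
        assert np.all(np.abs(mix[5:] - pop[5:]) / pop[5:] < 0.02)
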