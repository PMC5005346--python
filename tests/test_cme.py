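"""Stationary recursion, moments, modes, transients, and moment identities."""

import numpy as np
import pytest
from scipy.stats import nbinom, poisson

from burstmodes import (
    BurstyGeneModel,
    FeedbackFunction,
    analytic_extrema,
    find_extrema,
    get_preset,
    moment_ode_residuals,
    precision_profile,
    stationary_moments,
    stationary_pmf,
    taylor_mean_expansion,
    transient_cme,
)
from burstmodes.cme import stationary_pmf_nullspace

from conftest import random_model

PRESET_GRID = [
    (name, mu)
    for name in ("no_feedback", "noncoop", "coop_bistable", "coop_monostable_bimodal")
    for mu in (1, 6, 11)
]


def tv(p, q):
    L = max(len(p), len(q))
    a = np.zeros(L)
    b = np.zeros(L)
    a[: len(p)] = p
    b[: len(q)] = q
    return 0.5 * np.abs(a - b).sum()


class TestStationaryRecursion:
    def test_poisson_limit_without_bursts(self):
        """Constant production with unit bursts is the M/M/inf queue:
        stationary law Poisson(b/delta)."""
        m = get_preset("no_feedback", 1)
        p = stationary_pmf(m, tail_tol=1e-12)
        ref = poisson.pmf(np.arange(p.support), 20.0)
        assert tv(p.probs, ref) < 1e-12

    def test_negative_binomial_with_bursts(self):
        """Geometric bursts at constant rate give a negative binomial with
        r = b/(delta (mu*-1)) and success-complement q = 1 - 1/mu*."""
        for mu in (6.0, 11.0):
            m = get_preset("no_feedback", mu)
            p = stationary_pmf(m, tail_tol=1e-12)
            r = 20.0 / (mu - 1.0)
            q = 1.0 - 1.0 / mu
            ref = nbinom.pmf(np.arange(p.support), r, 1.0 - q)
            assert tv(p.probs, ref) < 1e-12

    def test_no_basal_production_collapses_to_extinction(self):
        f = FeedbackFunction.michaelis_menten(b=0.0, v=30.0, K=10.0)
        m = BurstyGeneModel(f=f, mu_star=6.0, delta=1.0)
        p = stationary_pmf(m)
        assert p.support == 1
        assert p.probs[0] == 1.0

    def test_recursion_ratio_identity(self, rng):
        """p_{n+1}/p_n equals [f(n)/(delta mu*) + n (mu*-1)/mu*]/(n+1)."""
        for _ in range(5):
            m = random_model(rng)
            p = stationary_pmf(m).probs
            n = np.arange(len(p) - 1, dtype=float)
            expected = (
                m.f(n) / (m.delta * m.mu_star) + n * (m.mu_star - 1) / m.mu_star
            ) / (n + 1)
            mask = p[:-1] > 1e-250
            np.testing.assert_allclose(
                p[1:][mask] / p[:-1][mask], expected[mask], rtol=1e-9
            )

    def test_normalized_and_tail_bounded(self, rng):
        for _ in range(5):
            m = random_model(rng)
            p = stationary_pmf(m, tail_tol=1e-10)
            assert p.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p.probs >= 0.0)
            assert p.truncation_tail < 1e-10

    def test_cap_exceeded_is_reported(self):
        m = get_preset("no_feedback", 6)
        with pytest.raises(RuntimeError, match="n_cap"):
            stationary_pmf(m, tail_tol=1e-12, n_cap=50)

    def test_matches_generator_nullspace(self, rng):
        """Cross-check against the truncated-generator null-space solve."""
        for _ in range(5):
            m = random_model(rng)
            p = stationary_pmf(m, tail_tol=1e-12)
            q = stationary_pmf_nullspace(m, p.support + 20)
            assert tv(p.probs, q) < 1e-8


class TestMoments:
    @pytest.mark.parametrize("name, mu", PRESET_GRID)
    def test_mean_balance_identity(self, name, mu):
        """E[N] = E[f(N)]/delta in steady state."""
        m = get_preset(name, mu)
        mom = stationary_moments(stationary_pmf(m), m)
        assert abs(mom.mean - mom.mean_f / m.delta) < 1e-9 * max(mom.mean, 1.0)

    @pytest.mark.parametrize("name, mu", PRESET_GRID)
    def test_variance_identity(self, name, mu):
        """var = mu* E[N] + Cov(N, f(N))/delta in steady state."""
        m = get_preset(name, mu)
        mom = stationary_moments(stationary_pmf(m), m)
        rhs = m.mu_star * mom.mean + mom.cov_nf / m.delta
        assert mom.variance == pytest.approx(rhs, rel=1e-8)

    @pytest.mark.parametrize("mu", [1.0, 6.0, 11.0])
    def test_fano_factor_equals_burst_size_for_constant_f(self, mu):
        m = get_preset("no_feedback", mu)
        mom = stationary_moments(stationary_pmf(m), m)
        assert mom.variance / mom.mean == pytest.approx(mu, rel=1e-8)
        assert mom.cov_nf == pytest.approx(0.0, abs=1e-12)


class TestExtrema:
    def test_strictly_decreasing_pmf_single_boundary_maximum(self):
        f = FeedbackFunction.constant(2.0)
        m = BurstyGeneModel(f=f, mu_star=6.0, delta=1.0)  # b/delta < mu*
        ext = find_extrema(stationary_pmf(m))
        assert ext.maxima == ((0, 0),)
        assert ext.minima == ()
        assert ext.boundary_extremum_at_zero == "maximum"

    def test_poisson_integer_mean_tie_plateau(self):
        """Poisson(20): p_19 = p_20 exactly, one two-point plateau."""
        m = get_preset("no_feedback", 1)
        ext = find_extrema(stationary_pmf(m))
        assert ext.maxima == ((19, 20),)

    def test_interior_mode_location(self):
        # b/delta = 20.5, mu* = 6: ratio crosses 1 at n = 14.5 -> mode at 15
        f = FeedbackFunction.constant(20.5)
        m = BurstyGeneModel(f=f, mu_star=6.0, delta=1.0)
        pmf = stationary_pmf(m)
        assert find_extrema(pmf).maxima == ((15, 15),)
        assert analytic_extrema(m, pmf.support).maxima == ((15, 15),)

    def test_analytic_ceiling_condition_for_constant_f(self):
        """Mode candidate n = ceil(b/delta - mu*)."""
        for b, mu in ((20.5, 6.0), (20.0, 11.0), (33.0, 2.0)):
            m = BurstyGeneModel(
                f=FeedbackFunction.constant(b), mu_star=mu, delta=1.0
            )
            ext = analytic_extrema(m, 200)
            expected = int(np.ceil(b - mu))
            assert ext.maxima[0][0] in (expected, expected - 1)  # tie plateau

    def test_burst_size_shifts_modes_left(self):
        locs = []
        for mu in (1.0, 6.0, 11.0):
            m = get_preset("no_feedback", mu)
            locs.append(find_extrema(stationary_pmf(m)).maxima[-1][0])
        assert locs[0] > locs[1] > locs[2]

    def test_analytic_matches_pmf_scan_on_random_models(self, rng):
        for _ in range(20):
            m = random_model(rng)
            pmf = stationary_pmf(m)
            a = find_extrema(pmf)
            b = analytic_extrema(m, pmf.support + 5)
            assert a.maxima == b.maxima
            assert a.minima == b.minima


class TestPrecisionProfile:
    @pytest.mark.parametrize("name, mu", [("noncoop", 6), ("no_feedback", 6)])
    def test_matches_pmf_relative_increments(self, name, mu):
        m = get_preset(name, mu)
        pmf = stationary_pmf(m)
        s = precision_profile(m, pmf)
        p = pmf.probs
        mask = p[:-1] > 1e-250
        rel = (p[1:] - p[:-1])[mask] / p[:-1][mask]
        assert np.max(np.abs(rel - s[:-1][mask])) < 1e-9

    def test_sign_changes_at_extrema(self):
        m = get_preset("noncoop", 6)
        pmf = stationary_pmf(m)
        s = precision_profile(m, pmf)
        ext = find_extrema(pmf)
        for lo, hi in ext.minima:
            assert s[lo - 1] < 0 < s[hi]


class TestTransient:
    def test_absorbing_empty_state_is_invariant(self):
        """No production and an empty state: the generator does nothing."""
        m = BurstyGeneModel(f=FeedbackFunction.constant(0.0), mu_star=1.0, delta=1.0)
        p0 = np.zeros(11)
        p0[0] = 1.0
        sol = transient_cme(m, p0, np.linspace(0, 5, 6), n_cap=10)
        assert sol.pmfs[-1][0] == pytest.approx(1.0, abs=1e-9)

    def test_probability_conservation(self):
        m = get_preset("noncoop", 6)
        n_cap = stationary_pmf(m).support + 40
        p0 = np.zeros(n_cap + 1)
        p0[0] = 1.0
        sol = transient_cme(m, p0, np.linspace(0, 10, 6), n_cap=n_cap)
        totals = sol.pmfs.sum(axis=1) + sol.leaked
        np.testing.assert_allclose(totals, 1.0, atol=1e-8)

    def test_convergence_to_stationary_unimodal(self):
        """From a point mass, the CME relaxes onto the recursion PMF."""
        m = get_preset("no_feedback", 6)
        pmf = stationary_pmf(m)
        n_cap = pmf.support + 40
        p0 = np.zeros(n_cap + 1)
        p0[0] = 1.0
        sol = transient_cme(m, p0, np.linspace(0, 40.0, 5), n_cap=n_cap)
        assert tv(sol.pmfs[-1], pmf.probs) < 1e-6

    def test_convergence_to_stationary_bimodal_long_horizon(self):
        """Bimodal systems mix on the inter-basin switching timescale, so the
        horizon must exceed the MFPT scale (here 200/delta)."""
        m = get_preset("noncoop", 6)
        pmf = stationary_pmf(m)
        n_cap = pmf.support + 40
        p0 = np.zeros(n_cap + 1)
        p0[0] = 1.0
        sol = transient_cme(m, p0, np.linspace(0, 200.0, 5), n_cap=n_cap)
        assert tv(sol.pmfs[-1], pmf.probs) < 1e-6

    def test_leak_error_advises_larger_cap(self):
        m = get_preset("no_feedback", 11)
        p0 = np.zeros(31)
        p0[0] = 1.0
        with pytest.raises(RuntimeError, match="n_cap"):
            transient_cme(m, p0, np.linspace(0, 40, 5), n_cap=30)


class TestMomentODEs:
    @pytest.mark.parametrize("name, mu", [("no_feedback", 6), ("noncoop", 6)])
    def test_mean_and_variance_equations_hold(self, name, mu):
        m = get_preset(name, mu)
        n_cap = stationary_pmf(m).support + 40
        p0 = np.zeros(n_cap + 1)
        p0[int(5)] = 1.0
        sol = transient_cme(m, p0, np.linspace(0, 10, 11), n_cap=n_cap)
        res = moment_ode_residuals(m, sol)
        assert res["mean_rel"] < 1e-6
        assert res["var_rel"] < 1e-6

    def test_linear_feedback_mean_matches_ode_exactly(self):
        """For linear f the CME mean obeys the deterministic ODE exactly."""
        from burstmodes import integrate_ode

        f = FeedbackFunction.linear(10.0, 0.3)
        m = BurstyGeneModel(f=f, mu_star=6.0, delta=1.0)
        n_cap = 400
        p0 = np.zeros(n_cap + 1)
        p0[0] = 1.0
        t = np.linspace(0, 8, 9)
        sol = transient_cme(m, p0, t, n_cap=n_cap)
        means = sol.pmfs @ np.arange(n_cap + 1)
        ode = integrate_ode(m, 0.0, t)
        np.testing.assert_allclose(means, ode, rtol=1e-6, atol=1e-6)

    def test_nonlinear_feedback_biases_mean_and_bursting_enlarges_it(self):
        """With saturating feedback the deterministic value deviates from the
        stationary mean, and larger bursts widen the gap."""
        from burstmodes import find_fixed_points

        gaps = []
        for mu in (1.0, 6.0, 11.0):
            m = get_preset("coop_monostable_bimodal", mu)
            mom = stationary_moments(stationary_pmf(m), m)
            c_star = find_fixed_points(m).stable[0].n_star
            gaps.append(abs(c_star - mom.mean))
        assert gaps[0] > 0.0
        assert gaps[0] < gaps[1] < gaps[2]


class TestTaylorExpansion:
    def test_exact_for_constant_and_linear(self):
        for f in (FeedbackFunction.constant(20.0), FeedbackFunction.linear(5.0, 0.4)):
            m = BurstyGeneModel(f=f, mu_star=6.0, delta=1.0)
            pmf = stationary_pmf(m)
            mom = stationary_moments(pmf, m)
            for order in (1, 2, 4):
                assert taylor_mean_expansion(m, pmf, order) == pytest.approx(
                    mom.mean_f, rel=1e-9
                )

    def test_exact_truncation_for_quadratic(self):
        # concave quadratic, increasing over the whole stationary support
        quad = FeedbackFunction.custom(
            lambda n: 2.0 + 0.4 * np.asarray(n) - 0.002 * np.asarray(n) ** 2,
            b=2.0,
        )
        m = BurstyGeneModel(f=quad, mu_star=3.0, delta=1.0)
        pmf = stationary_pmf(m)
        mom = stationary_moments(pmf, m)
        assert taylor_mean_expansion(m, pmf, 2) == pytest.approx(mom.mean_f, rel=1e-6)

    def test_error_shrinks_with_order_on_unimodal_hill(self):
        m = get_preset("coop_monostable_bimodal", 1)  # unimodal at mu*=1
        pmf = stationary_pmf(m)
        mom = stationary_moments(pmf, m)
        errs = [
            abs(taylor_mean_expansion(m, pmf, order) - mom.mean_f)
            for order in (1, 4)
        ]
        assert errs[1] < errs[0]
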