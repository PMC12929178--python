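import numpy as np
import pytest

from clpntraj.trajectories import (
    _fit_single_class,
    blrt,
    enumerate_classes,
    fit_lcga,
    fit_pp_lgcm,
    relative_entropy,
    simulate_from_solution,
)


class TestPPLGCM:
    def test_near_noiseless_growth_is_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 400
        t = np.arange(3)
        b = rng.multivariate_normal([0.8, 0.2, 1.0, 0.25],
                                    np.diag([0.09, 0.01, 0.09, 0.01]), n)
        y = np.hstack([b[:, :1] + b[:, 1:2] * t, b[:, 2:3] + b[:, 3:] * t])
        y += rng.normal(0, 0.01, y.shape)
        fit = fit_pp_lgcm(y)
        assert np.abs(fit.mu - [0.8, 0.2, 1.0, 0.25]).max() < 0.03
        assert fit.theta.max() < 5e-4
        # a correctly specified model leaves only df ~ chi2_7 worth of misfit
        assert fit.t_stat < 30.0
        assert fit.rmsea == pytest.approx(0.0, abs=0.05)

    def test_intercept_correlation_recovery(self):
        rng = np.random.default_rng(1)
        n = 3000
        psi = np.diag([0.10, 0.012, 0.10, 0.012])
        rho = 0.4
        psi[0, 2] = psi[2, 0] = rho * 0.10
        b = rng.multivariate_normal([0.7, 0.1, 0.9, 0.15], psi, n)
        t = np.arange(3)
        y = np.hstack([b[:, :1] + b[:, 1:2] * t, b[:, 2:3] + b[:, 3:] * t])
        y += rng.normal(0, 0.25, y.shape)
        fit = fit_pp_lgcm(y)
        assert fit.r_intercept == pytest.approx(rho, abs=0.05)
        # diagonal-Psi truth elsewhere: slope-slope correlation near zero
        assert abs(fit.r_slope) < 0.12
        assert fit.cfi > 0.95 and fit.tli <= 1.0
        assert np.all(np.linalg.eigvalsh(fit.psi) > -1e-8)


class TestLCGA:
    def test_single_class_em_matches_closed_form(self, growth_y):
        theta, s2, ll = _fit_single_class(growth_y)
        sol = fit_lcga(growth_y, 1)
        assert sol.loglik == pytest.approx(ll, abs=1e-8 * abs(ll))
        assert np.allclose(sol.means[0], theta, atol=1e-8)
        assert np.allclose(sol.sigma2, s2, atol=1e-10)

    def test_three_class_recovery_and_entropy(self, growth_y):
        sol = fit_lcga(growth_y, 3, n_restarts=4, seed=0)
        # classes canonicalized by ascending severity: means near the truth
        truth = np.array([[0.4, 0.02, 0.5, 0.03],
                          [1.3, 0.25, 1.5, 0.30],
                          [2.2, 0.05, 2.3, 0.05]])
        assert np.abs(sol.means - truth).max() < 0.06
        assert sol.entropy > 0.80
        assert sol.pi == pytest.approx([0.6, 0.3, 0.1], abs=0.03)

    def test_em_loglik_monotone(self, growth_y):
        sol = fit_lcga(growth_y, 3, n_restarts=2, seed=1)
        diffs = np.diff(sol.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(sol.loglik)).all()

    def test_information_criteria_formulas(self, growth_y):
        sol = fit_lcga(growth_y, 2, n_restarts=2, seed=2)
        n, q, ll = sol.n, sol.n_params, sol.loglik
        assert q == 4 * 2 + 2 + 1
        assert sol.aic == pytest.approx(-2 * ll + 2 * q)
        assert sol.bic == pytest.approx(-2 * ll + q * np.log(n))
        assert sol.abic == pytest.approx(-2 * ll + q * np.log((n + 2) / 24))
        assert sol.abic < sol.bic  # holds whenever n > 22

    def test_posteriors_normalized_and_pi_consistent(self, growth_y):
        sol = fit_lcga(growth_y, 3, n_restarts=2, seed=3)
        assert np.allclose(sol.posteriors.sum(axis=1), 1.0)
        assert np.allclose(sol.posteriors.mean(axis=0), sol.pi, atol=1e-6)

    def test_restart_seed_invariance_after_canonicalization(self, growth_y):
        a = fit_lcga(growth_y, 3, n_restarts=3, seed=10)
        b = fit_lcga(growth_y, 3, n_restarts=5, seed=99)
        assert np.allclose(a.means, b.means, atol=1e-4)
        assert np.allclose(a.pi, b.pi, atol=1e-4)

    def test_k_must_be_positive(self, growth_y):
        with pytest.raises(ValueError):
            fit_lcga(growth_y, 0)


class TestEntropy:
    def test_hard_assignments_give_one(self):
        post = np.zeros((10, 3))
        post[np.arange(10), np.arange(10) % 3] = 1.0
        assert relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_posteriors_give_zero(self):
        for k in (2, 3, 5):
            post = np.full((20, k), 1.0 / k)
            assert relative_entropy(post) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_relabelling(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(3), size=50)
        assert relative_entropy(post) == pytest.approx(
            relative_entropy(post[:, [2, 0, 1]])
        )


class TestEnumeration:
    def test_table_shape_and_bic_prefers_truth(self, growth_y):
        table, fits = enumerate_classes(growth_y, k_max=4, n_restarts=2, seed=0)
        assert list(table.index) == [1, 2, 3, 4]
        assert int(table["BIC"].idxmin()) == 3
        assert np.isnan(table.loc[1, "entropy"])

    def test_blrt_rejects_under_clear_two_class_structure(self):
        rng = np.random.default_rng(5)
        n = 300
        t = np.arange(3)
        lab = rng.random(n) < 0.5
        y = np.where(lab[:, None], 0.5, 2.0) + np.zeros((n, 6))
        y[:, :3] += 0.1 * t
        y[:, 3:] += 0.2 * t
        y += rng.normal(0, 0.3, y.shape)
        lr, p = blrt(y, 2, reps=39, seed=6, n_restarts=2)
        assert lr > 0
        assert p == pytest.approx(1 / 40, abs=1e-12)

    def test_simulation_from_solution_matches_moments(self, growth_y):
        sol = fit_lcga(growth_y, 3, n_restarts=2, seed=4)
        y = simulate_from_solution(sol, 20000, np.random.default_rng(7))
        assert np.abs(y.mean(0) - growth_y.mean(0)).max() < 0.03
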