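"""SEM kernel against closed-form and direct-density oracles."""

import math

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.stats import multivariate_normal

from gmlcs.sem_engine import (
    POOLED,
    FimlProblem,
    ModelSpec,
    fiml_neg2ll,
    fit,
    fit_indices,
    implied_moments,
    start_from,
)

G = POOLED


def one_factor_spec(n_ind=3, groups=(G,)):
    names = tuple(f"x{i+1}" for i in range(n_ind))
    spec = ModelSpec(manifest=names, latent=("f",), groups=groups)
    for g in groups:
        sfx = "" if len(groups) == 1 else f".{g}"
        spec.set_path(g, "f", names[0], 1.0)
        for i, x in enumerate(names[1:], start=2):
            spec.set_path(g, "f", x, f"l{i}{sfx}")
        spec.set_cov(g, "f", "f", f"psi{sfx}")
        for i, x in enumerate(names, start=1):
            spec.set_cov(g, x, x, f"th{i}{sfx}")
            spec.set_mean(g, x, f"m{i}{sfx}")
        spec.set_mean(g, "f", 0.0)
    return spec


def one_factor_moments(lam, psi, theta, mu):
    lam = np.asarray(lam)
    return np.asarray(mu), psi * np.outer(lam, lam) + np.diag(theta)


# ----------------------------------------------------------------------
# implied moments
# ----------------------------------------------------------------------
class TestImpliedMoments:
    def test_no_path_identity(self):
        spec = ModelSpec(manifest=("a", "b"), groups=(G,))
        spec.set_cov(G, "a", "a", 2.0)
        spec.set_cov(G, "b", "b", 3.0)
        spec.set_cov(G, "a", "b", "c")
        spec.set_mean(G, "a", 0.5)
        spec.set_mean(G, "b", 0.0)
        mu, sigma = implied_moments(spec, {"c": 1.5})[G]
        assert np.allclose(sigma, [[2.0, 1.5], [1.5, 3.0]])
        assert np.allclose(mu, [0.5, 0.0])
        assert np.allclose(sigma, sigma.T, atol=1e-12)

    def test_one_factor_closed_form(self):
        spec = one_factor_spec()
        vals = dict(l2=0.7, l3=-1.2, psi=0.9, th1=0.3, th2=0.5, th3=0.2,
                    m1=0.0, m2=1.0, m3=-1.0)
        mu, sigma = implied_moments(spec, vals)[G]
        mu_o, sigma_o = one_factor_moments(
            [1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2], [0.0, 1.0, -1.0]
        )
        assert np.allclose(sigma, sigma_o) and np.allclose(mu, mu_o)

    def test_lcsm_mean_expansion(self):
        """With the difference path fixed to 1, the implied occasion-2 mean
        is intercept + (mu_eta1 + mu_delta) * loading."""
        spec = ModelSpec(manifest=("y1", "y2"), latent=("e1", "e2", "d"), groups=(G,))
        lam, tau, mu1, mud = 0.8, 0.3, 0.4, -0.1
        spec.set_path(G, "e1", "y1", lam)
        spec.set_path(G, "e2", "y2", lam)
        spec.set_path(G, "e1", "e2", 1.0)
        spec.set_path(G, "d", "e2", 1.0)
        for v in ("y1", "y2"):
            spec.set_cov(G, v, v, 0.1)
            spec.set_mean(G, v, tau)
        spec.set_cov(G, "e1", "e1", 1.0)
        spec.set_cov(G, "e2", "e2", 0.0)
        spec.set_cov(G, "d", "d", 0.2)
        spec.set_mean(G, "e1", mu1)
        spec.set_mean(G, "e2", 0.0)
        spec.set_mean(G, "d", mud)
        mu, _ = implied_moments(spec, {})[G]
        assert mu[1] == pytest.approx(tau + (mu1 + mud) * lam)

    def test_singular_paths_error(self):
        spec = ModelSpec(manifest=("a", "b"), groups=(G,))
        spec.set_path(G, "a", "b", 1.0)
        spec.set_path(G, "b", "a", 1.0)  # cycle with unit product
        spec.set_cov(G, "a", "a", 1.0)
        spec.set_cov(G, "b", "b", 1.0)
        with pytest.raises(np.linalg.LinAlgError, match="cycle|singular"):
            implied_moments(spec, {})


# ----------------------------------------------------------------------
# FIML objective
# ----------------------------------------------------------------------
class TestFimlNeg2ll:
    VALS = dict(l2=0.7, l3=-1.2, psi=0.9, th1=0.3, th2=0.5, th3=0.2,
                m1=0.0, m2=1.0, m3=-1.0)

    def test_univariate_closed_form(self):
        spec = ModelSpec(manifest=("x",), groups=(G,))
        spec.set_cov(G, "x", "x", 2.5)
        spec.set_mean(G, "x", 1.0)
        x = np.array([[2.0]])
        expected = math.log(2 * math.pi) + math.log(2.5) + (2.0 - 1.0) ** 2 / 2.5
        assert fiml_neg2ll(spec, {}, {G: x}) == pytest.approx(expected, abs=1e-12)

    def test_complete_data_equals_direct_density(self, rng):
        spec = one_factor_spec()
        mu, sigma = one_factor_moments([1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2],
                                       [0.0, 1.0, -1.0])
        x = rng.multivariate_normal(mu, sigma, 80)
        direct = -2.0 * multivariate_normal(mu, sigma).logpdf(x).sum()
        assert fiml_neg2ll(spec, self.VALS, {G: x}) == pytest.approx(direct, abs=1e-8)

    def test_duplicating_cases_doubles_value(self, rng):
        spec = one_factor_spec()
        mu, sigma = one_factor_moments([1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2],
                                       [0.0, 1.0, -1.0])
        x = rng.multivariate_normal(mu, sigma, 30)
        x[::4, 1] = np.nan  # include a missingness pattern
        one = fiml_neg2ll(spec, self.VALS, {G: x})
        two = fiml_neg2ll(spec, self.VALS, {G: np.vstack([x, x])})
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_pattern_grouping_matches_case_by_case(self, rng):
        """The pattern-grouped objective is contractually identical to a
        case-by-case marginal-density evaluation."""
        spec = one_factor_spec()
        mu, sigma = one_factor_moments([1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2],
                                       [0.0, 1.0, -1.0])
        x = rng.multivariate_normal(mu, sigma, 60)
        mask = rng.random(x.shape) < 0.3
        mask[mask.all(axis=1)] = False  # keep >= 1 observed per case
        x[mask] = np.nan
        total = 0.0
        for row in x:
            obs = ~np.isnan(row)
            total += -2.0 * multivariate_normal(
                mu[obs], sigma[np.ix_(obs, obs)]
            ).logpdf(row[obs])
        assert fiml_neg2ll(spec, self.VALS, {G: x}) == pytest.approx(total, abs=1e-8)

    def test_invariant_to_case_and_variable_order(self, rng):
        spec = one_factor_spec()
        mu, sigma = one_factor_moments([1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2],
                                       [0.0, 1.0, -1.0])
        x = rng.multivariate_normal(mu, sigma, 50)
        x[::5, 2] = np.nan
        base = fiml_neg2ll(spec, self.VALS, {G: x})
        shuffled = x[rng.permutation(len(x))]
        assert fiml_neg2ll(spec, self.VALS, {G: shuffled}) == pytest.approx(base, rel=1e-14)
        # reorder variables consistently in spec and data
        perm = [2, 0, 1]
        spec2 = ModelSpec(manifest=tuple(spec.manifest[i] for i in perm),
                          latent=("f",), groups=(G,))
        spec2.A[G] = dict(spec.A[G])
        spec2.S[G] = dict(spec.S[G])
        spec2.M[G] = dict(spec.M[G])
        assert fiml_neg2ll(spec2, self.VALS, {G: x[:, perm]}) == pytest.approx(base, rel=1e-14)

    def test_nonpd_sigma_gives_infinite_objective(self):
        spec = ModelSpec(manifest=("a", "b"), groups=(G,))
        spec.set_cov(G, "a", "a", 1.0)
        spec.set_cov(G, "b", "b", 1.0)
        spec.set_cov(G, "a", "b", "c")
        spec.set_mean(G, "a", 0.0)
        spec.set_mean(G, "b", 0.0)
        val = fiml_neg2ll(spec, {"c": 1.5}, {G: np.zeros((3, 2))})
        assert np.isinf(val)

    def test_gradient_of_grouped_objective_matches_casewise_oracle(self, rng):
        """Finite-difference gradients of the pattern-grouped objective and
        of a case-by-case direct-density oracle agree."""
        spec = one_factor_spec()
        mu, sigma = one_factor_moments([1, 0.7, -1.2], 0.9, [0.3, 0.5, 0.2],
                                       [0.0, 1.0, -1.0])
        x = rng.multivariate_normal(mu, sigma, 40)
        x[::3, 0] = np.nan
        prob = FimlProblem(spec, {G: x})
        labels = prob.labels
        theta0 = np.array([self.VALS[l] for l in labels])

        def casewise(theta):
            vals = dict(zip(labels, theta))
            mu_i, sig_i = implied_moments(spec, vals)[G]
            total = 0.0
            for row in x:
                obs = ~np.isnan(row)
                total += -2.0 * multivariate_normal(
                    mu_i[obs], sig_i[np.ix_(obs, obs)]
                ).logpdf(row[obs])
            return total

        g1 = optimize.approx_fprime(theta0, prob.neg2ll, 1e-6)
        g2 = optimize.approx_fprime(theta0, casewise, 1e-6)
        assert np.allclose(g1, g2, rtol=1e-5, atol=1e-6)


# ----------------------------------------------------------------------
# estimation
# ----------------------------------------------------------------------
class TestFit:
    def test_saturated_model_recovers_ml_moments(self, rng):
        """A saturated spec on complete data: chi-square 0 and estimates
        equal to the n-denominator sample moments."""
        x = rng.multivariate_normal([1.0, -0.5], [[2.0, 0.6], [0.6, 1.0]], 120)
        spec = ModelSpec(manifest=("a", "b"), groups=(G,))
        spec.set_cov(G, "a", "a", "vaa")
        spec.set_cov(G, "b", "b", "vbb")
        spec.set_cov(G, "a", "b", "vab")
        spec.set_mean(G, "a", "ma")
        spec.set_mean(G, "b", "mb")
        res = fit(spec, {G: x}, restarts=1, seed=0)
        assert res.converged
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        mu = x.mean(axis=0)
        s = (x - mu).T @ (x - mu) / len(x)
        assert res.estimates["ma"] == pytest.approx(mu[0], abs=1e-5)
        assert res.estimates["mb"] == pytest.approx(mu[1], abs=1e-5)
        assert res.estimates["vaa"] == pytest.approx(s[0, 0], rel=1e-4)
        assert res.estimates["vab"] == pytest.approx(s[0, 1], rel=1e-4)

    def test_two_occasion_difference_model_equals_arithmetic(self, rng):
        """Exactly identified difference model: the latent change mean is
        the occasion-mean difference."""
        x1 = rng.normal(0, 1, 70)
        x2 = x1 + rng.normal(0.4, 0.5, 70)
        spec = ModelSpec(manifest=("x1", "x2"), latent=("d",), groups=(G,))
        spec.set_path(G, "x1", "x2", 1.0)
        spec.set_path(G, "d", "x2", 1.0)
        spec.set_cov(G, "x1", "x1", "v1")
        spec.set_cov(G, "d", "d", "vd")
        spec.set_cov(G, "x1", "d", "c")
        spec.set_cov(G, "x2", "x2", 0.0)
        spec.set_mean(G, "x1", "m1")
        spec.set_mean(G, "d", "md")
        spec.set_mean(G, "x2", 0.0)
        res = fit(spec, {G: np.column_stack([x1, x2])}, restarts=1, seed=0)
        assert res.df == 0
        assert res.estimates["md"] == pytest.approx(float(np.mean(x2 - x1)), abs=1e-6)

    def test_no_missing_fiml_equals_complete_data_ml(self, rng):
        """On random small one-factor models, the FIML optimum with no
        missingness equals the complete-data ML optimum found by directly
        optimizing the closed-form MVN likelihood."""
        for trial in range(5):
            lam = rng.uniform(0.5, 1.5, 2) * rng.choice([-1, 1], 2)
            theta_t = rng.uniform(0.2, 0.8, 3)
            mu_t = rng.normal(0, 1, 3)
            mu, sigma = one_factor_moments([1, *lam], rng.uniform(0.5, 1.5),
                                           theta_t, mu_t)
            x = rng.multivariate_normal(mu, sigma, 150)
            spec = one_factor_spec()
            res = fit(spec, {G: x}, restarts=1, seed=trial,
                      indices=False, standard_errors=False)

            labels = list(res.estimates)

            def direct(vec):
                vals = dict(zip(labels, vec))
                m, s = implied_moments(spec, vals)[G]
                try:
                    return -2.0 * multivariate_normal(m, s).logpdf(x).sum()
                except (np.linalg.LinAlgError, ValueError):
                    return 1e12

            direct_opt = optimize.minimize(
                direct, np.array([res.estimates[l] for l in labels]),
                method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000},
            )
            assert res.neg2ll == pytest.approx(direct_opt.fun, abs=1e-6)
            assert res.neg2ll <= direct_opt.fun + 1e-6

    def test_single_rep_parameter_recovery(self, rng):
        lam_t, psi_t, theta_t = [1.0, 0.8, -1.1], 1.0, [0.4, 0.4, 0.3]
        mu, sigma = one_factor_moments(lam_t, psi_t, theta_t, [0.0, 0.0, 0.0])
        x = rng.multivariate_normal(mu, sigma, 500)
        res = fit(one_factor_spec(), {G: x}, restarts=1, seed=0, indices=False)
        for lbl, truth in (("l2", 0.8), ("l3", -1.1), ("psi", 1.0), ("th2", 0.4)):
            assert abs(res.estimates[lbl] - truth) < 3 * res.se[lbl], lbl

    def test_chi_square_monotone_under_constraints(self, rng):
        mu, sigma = one_factor_moments([1, 0.8, 0.9], 1.0, [0.4, 0.4, 0.4],
                                       [0.1, 0.1, 0.1])
        x = rng.multivariate_normal(mu, sigma, 100)
        parent_spec = one_factor_spec()
        parent = fit(parent_spec, {G: x}, restarts=1, seed=0, standard_errors=False)
        child_spec = parent_spec.merge_labels({"l2": "l", "l3": "l"})
        child = fit(child_spec, {G: x}, restarts=1, seed=0,
                    start=start_from(parent, child_spec), standard_errors=False)
        assert child_spec.nested_within(parent_spec)
        assert child.chi_square >= parent.chi_square - 1e-6

    def test_unidentified_model_rejected(self):
        spec = one_factor_spec()
        spec.set_cov(G, "x1", "x2", "extra1")
        spec.set_cov(G, "x1", "x3", "extra2")  # now 11 params > 9 moments
        with pytest.raises(ValueError, match="not identified"):
            fit(spec, {G: np.zeros((5, 3))})

    def test_nonconvergence_is_reported_not_silent(self, rng):
        # one optimizer iteration cannot converge from a cold start
        x = rng.multivariate_normal(*one_factor_moments([1, 0.8, 0.9], 1.0,
                                    [0.4, 0.4, 0.4], [0, 0, 0]), size=60)
        res = fit(one_factor_spec(), {G: x}, restarts=1, seed=0,
                  indices=False, standard_errors=False, ftol=1e-30)
        # with an unattainable tolerance the optimizer stops on maxiter and
        # must say so rather than pretend convergence
        if not res.converged:
            assert any("converge" in d for d in res.diagnostics)


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
class TestFitIndices:
    def test_perfect_fit(self):
        rmsea, ci, cfi = fit_indices(10.0, 10, 101, 200.0, 15)
        assert rmsea == 0.0 and cfi == 1.0 and ci[0] == 0.0

    def test_arithmetic_oracle(self):
        rmsea, _, _ = fit_indices(20.0, 10, 101, 300.0, 15)
        assert rmsea == pytest.approx(math.sqrt(10.0 / 1000.0))
        assert rmsea == pytest.approx(0.1)

    def test_noncentral_inversion_round_trip(self):
        chi2, df, n = 37.5, 12, 140
        rmsea, (lo, hi), _ = fit_indices(chi2, df, n, 400.0, 20)
        lam_u = hi**2 * df * (n - 1)
        lam_l = lo**2 * df * (n - 1)
        assert stats.ncx2.cdf(chi2, df, lam_u) == pytest.approx(0.025, abs=1e-6)
        assert stats.ncx2.cdf(chi2, df, lam_l) == pytest.approx(0.975, abs=1e-6)
        assert lo <= rmsea <= hi

    def test_cfi_bounds(self):
        *_, cfi = fit_indices(50.0, 10, 101, 45.0, 15)  # worse than baseline
        assert 0.0 <= cfi <= 1.0


# ----------------------------------------------------------------------
# standardized solution
# ----------------------------------------------------------------------
class TestStandardize:
    def _fit_with(self, rng, lam2, psi, th):
        mu, sigma = one_factor_moments([1, lam2, 0.9], psi, [0.3, th, 0.4],
                                       [0, 0, 0])
        x = rng.multivariate_normal(mu, sigma, 400)
        return fit(one_factor_spec(), {G: x}, restarts=1, seed=0,
                   indices=False, standard_errors=False)

    def test_unit_case_and_closed_form(self):
        """lambda = 0.8, psi = 1, theta = 0.36: implied manifest variance 1,
        standardized loading exactly 0.8 at the population values."""
        spec = one_factor_spec()
        vals = dict(l2=0.8, l3=0.8, psi=1.0, th1=0.36, th2=0.36, th3=0.36,
                    m1=0.0, m2=0.0, m3=0.0)
        from gmlcs.sem_engine import FitResult, standardize_solution

        res = FitResult(spec=spec, estimates=vals, se={}, neg2ll=0.0,
                        n_params=9, n_obs=0, converged=True)
        std = standardize_solution(res, spec)
        assert std["l2"] == pytest.approx(0.8 / math.sqrt(0.8**2 + 0.36))
        assert std["l2"] == pytest.approx(0.8)

    def test_covariance_beyond_unit_reported_with_warning(self):
        spec = ModelSpec(manifest=("a", "b"), latent=(), groups=(G,))
        spec.set_cov(G, "a", "a", 1.0)
        spec.set_cov(G, "b", "b", 1.0)
        spec.set_cov(G, "a", "b", "c")
        spec.set_mean(G, "a", 0.0)
        spec.set_mean(G, "b", 0.0)
        from gmlcs.sem_engine import FitResult, standardize_solution

        res = FitResult(spec=spec, estimates={"c": 1.11}, se={}, neg2ll=0.0,
                        n_params=1, n_obs=0, converged=True)
        std = standardize_solution(res, spec)
        assert std["c"] == pytest.approx(1.11)  # not clipped
        assert any("exceeds |1|" in d for d in res.diagnostics)
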