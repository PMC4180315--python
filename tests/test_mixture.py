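"""Mixture likelihoods, EM fitting, posteriors, thresholds, model comparison.

Independent oracles used here: closed-form likelihood values on tiny inputs,
scipy quadrature for density normalization, sklearn's Gaussian-mixture EM for
the no-zeros case, and direct multi-start numerical maximization of the same
likelihoods.
"""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from methicc import (
    MixtureFit,
    censored_mixture_loglik,
    classify_sites,
    compare_models,
    fit_censored_mixture,
    fit_truncated_mixture,
    icc_threshold_for_posterior,
    posterior_high,
    simulate_icc_sample,
    truncated_mixture_loglik,
)


def _fit(kind="censored", **kw):
    base = dict(p=0.5, mu1=0.1, sigma1=0.1, mu2=0.7, sigma2=0.1, loglik=0.0,
                n_iter=0, converged=True, n_obs=0)
    base.update(kw)
    return MixtureFit(model_kind=kind, **base)


class TestCensoredLoglik:
    def test_four_zeros_analytic(self):
        fit = _fit(p=1.0, mu1=0.0, sigma1=1.0)
        ll = censored_mixture_loglik(fit, np.zeros(4))
        assert ll == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_degenerate_mixture_is_plain_normal(self, rng):
        x = rng.normal(0.7, 0.1, 50).clip(0.01, 1)
        fit = _fit(p=0.0, mu2=0.7, sigma2=0.1)
        assert censored_mixture_loglik(fit, x) == pytest.approx(
            stats.norm.logpdf(x, 0.7, 0.1).sum(), abs=1e-9
        )

    def test_published_parameters_match_entropy_oracle(self):
        """Mean log likelihood per observation under the published censored
        parameters equals the (Monte-Carlo) differential entropy of the
        generating distribution, up to MC error."""
        fit = _fit(p=0.55, mu1=0.15, sigma1=0.14, mu2=0.67, sigma2=0.14)
        rng = np.random.default_rng(0)
        comp = rng.random(50_000) < 0.55
        raw = np.where(comp, rng.normal(0.15, 0.14, 50_000), rng.normal(0.67, 0.14, 50_000))
        x = np.maximum(raw, 0.0)  # censor at zero
        mean_ll = censored_mixture_loglik(fit, x) / x.size
        # oracle: independent MC estimate of E[log f] from a fresh sample
        rng2 = np.random.default_rng(1)
        comp2 = rng2.random(50_000) < 0.55
        raw2 = np.where(comp2, rng2.normal(0.15, 0.14, 50_000), rng2.normal(0.67, 0.14, 50_000))
        x2 = np.maximum(raw2, 0.0)
        oracle = censored_mixture_loglik(fit, x2) / x2.size
        assert mean_ll == pytest.approx(oracle, abs=0.02)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            censored_mixture_loglik(_fit(sigma1=0.0), np.array([0.5]))


class TestTruncatedLoglik:
    def test_reduces_to_plain_normal(self, rng):
        x = rng.normal(0.7, 0.1, 40).clip(0.01, 0.99)
        fit = _fit("truncated", p=0.0, mu2=0.7, sigma2=0.1, p0=0.0)
        assert truncated_mixture_loglik(fit, x, n0=0) == pytest.approx(
            stats.norm.logpdf(x, 0.7, 0.1).sum(), abs=1e-9
        )

    def test_single_point_analytic(self):
        mu1, s1 = 0.3, 0.2
        fit = _fit("truncated", p=1.0, mu1=mu1, sigma1=s1, p0=0.0)
        expected = math.log(
            stats.norm.pdf(0.0) / (s1 * (1 - stats.norm.cdf(-mu1 / s1)))
        )
        assert truncated_mixture_loglik(fit, np.array([mu1]), n0=0) == pytest.approx(expected, abs=1e-12)

    def test_zero_term_uses_sample_proportion(self):
        fit = _fit("truncated", p=0.5, p0=0.25)
        x = np.array([0.1, 0.7, 0.75])
        ll = truncated_mixture_loglik(fit, x, n0=1)
        fit0 = _fit("truncated", p=0.5, p0=0.25)
        base = truncated_mixture_loglik(fit0, x, n0=0)
        assert ll == pytest.approx(base + math.log(0.25), abs=1e-12)


class TestDensityNormalization:
    def test_censored_total_mass_is_one(self):
        fit = _fit(p=0.55, mu1=0.15, sigma1=0.14, mu2=0.67, sigma2=0.14)
        point_mass = 0.55 * stats.norm.cdf(0, 0.15, 0.14) + 0.45 * stats.norm.cdf(0, 0.67, 0.14)
        dens = lambda x: (0.55 * stats.norm.pdf(x, 0.15, 0.14) + 0.45 * stats.norm.pdf(x, 0.67, 0.14))
        cont, err = integrate.quad(dens, 0, np.inf)
        assert point_mass + cont == pytest.approx(1.0, abs=1e-6)

    def test_truncated_total_mass_is_one(self, published_truncated_fit):
        f = published_truncated_fit
        tn = lambda x: stats.norm.pdf(x, f.mu1, f.sigma1) / stats.norm.sf(0, f.mu1, f.sigma1)
        dens = lambda x: f.p1 * tn(x) + f.p2 * stats.norm.pdf(x, f.mu2, f.sigma2)
        cont, err = integrate.quad(dens, 0, np.inf)
        assert f.p0 + cont == pytest.approx(1.0, abs=1e-6)


class TestCensoredEM:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 20_000
        comp = rng.random(n) < 0.4
        raw = np.where(comp, rng.normal(0.1, 0.1, n), rng.normal(0.7, 0.1, n))
        x = np.clip(raw, 0.0, 1.0)
        assert (x == 0).mean() > 0.05  # ~10% censored at these parameters
        fit = fit_censored_mixture(x, seed=0)
        assert fit.converged
        assert fit.p == pytest.approx(0.4, abs=0.03)
        assert fit.mu1 == pytest.approx(0.1, abs=0.03)
        assert fit.sigma1 == pytest.approx(0.1, abs=0.03)
        assert fit.mu2 == pytest.approx(0.7, abs=0.03)
        assert fit.sigma2 == pytest.approx(0.1, abs=0.03)

    def test_no_zeros_matches_gaussian_mixture_oracle(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        n = 5_000
        comp = rng.random(n) < 0.35
        x = np.where(comp, rng.normal(0.25, 0.05, n), rng.normal(0.75, 0.06, n)).clip(0.01, 0.99)
        fit = fit_censored_mixture(x, seed=0)
        gm = GaussianMixture(2, random_state=0, tol=1e-8, max_iter=2000).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.ravel()[order])
        weights = gm.weights_[order]
        assert fit.mu1 == pytest.approx(means[0], abs=0.01)
        assert fit.mu2 == pytest.approx(means[1], abs=0.01)
        assert fit.sigma1 == pytest.approx(sds[0], abs=0.01)
        assert fit.sigma2 == pytest.approx(sds[1], abs=0.01)
        assert fit.p == pytest.approx(weights[0], abs=0.01)

    def test_loglik_trace_non_decreasing(self, rng):
        x = np.clip(np.where(rng.random(2000) < 0.5, rng.normal(0.1, 0.15, 2000), rng.normal(0.6, 0.2, 2000)), 0, 1)
        fit = fit_censored_mixture(x, seed=0)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-7 * np.abs(trace[:-1])).all()

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_censored_mixture(np.linspace(0.1, 0.9, 50))


class TestTruncatedEM:
    def test_recovery_from_published_parameters(self):
        x = simulate_icc_sample(0.076, 0.67, 0.04, 0.28, 0.72, 0.11, n=50_000, seed=9)
        fit = fit_truncated_mixture(x, seed=0, n_restarts=1)
        assert fit.converged
        assert fit.p0 == pytest.approx(0.076, abs=0.001)
        assert fit.p == pytest.approx(0.67, abs=0.03)
        assert fit.mu1 == pytest.approx(0.04, abs=0.03)
        assert fit.sigma1 == pytest.approx(0.28, abs=0.05)
        assert fit.mu2 == pytest.approx(0.72, abs=0.03)
        assert fit.sigma2 == pytest.approx(0.11, abs=0.03)

    def test_all_zeros_degenerate(self):
        fit = fit_truncated_mixture(np.zeros(500))
        assert fit.degenerate
        assert fit.p0 == 1.0

    def test_two_well_separated_clumps(self, rng):
        x = np.concatenate([
            rng.normal(0.2, 0.01, 300).clip(0.001, 1),
            rng.normal(0.8, 0.01, 300).clip(0.001, 1),
        ])
        fit = fit_truncated_mixture(x, seed=0)
        lo, hi = sorted([fit.mu1, fit.mu2])
        assert lo == pytest.approx(0.2, abs=0.02)
        assert hi == pytest.approx(0.8, abs=0.02)

    def test_loglik_trace_non_decreasing(self):
        x = simulate_icc_sample(0.1, 0.5, 0.05, 0.2, 0.7, 0.1, n=3000, seed=5)
        fit = fit_truncated_mixture(x, seed=0)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-7 * np.abs(trace[:-1])).all()


class TestPosterior:
    def test_high_icc_strongly_high(self, published_truncated_fit):
        pi = posterior_high(published_truncated_fit, 0.9)
        # direct density evaluation: p2*g2/(p1*g1+p2*g2) at 0.9
        f = published_truncated_fit
        g1 = stats.norm.pdf(0.9, f.mu1, f.sigma1) / stats.norm.sf(0, f.mu1, f.sigma1)
        g2 = stats.norm.pdf(0.9, f.mu2, f.sigma2)
        oracle = (1 - f.p) * g2 / (f.p * g1 + (1 - f.p) * g2)
        assert pi == pytest.approx(oracle, abs=1e-10)
        assert pi > 0.95

    def test_posterior_near_cutoff_at_published_threshold(self, published_truncated_fit):
        assert posterior_high(published_truncated_fit, 0.37) == pytest.approx(0.01, abs=0.002)

    def test_pure_high_component(self):
        fit = _fit("truncated", p=0.0)
        assert posterior_high(fit, 0.3) == 1.0

    def test_zero_icc_rejected(self, published_truncated_fit):
        with pytest.raises(ValueError, match="ICC > 0"):
            posterior_high(published_truncated_fit, 0.0)


class TestThreshold:
    def test_published_threshold(self, published_truncated_fit):
        thr = icc_threshold_for_posterior(published_truncated_fit, 0.01)
        assert thr == pytest.approx(0.37, abs=0.01)

    def test_symmetric_fit_midpoint(self):
        fit = _fit("censored", p=0.5, mu1=0.3, sigma1=0.1, mu2=0.7, sigma2=0.1)
        assert icc_threshold_for_posterior(fit, 0.5) == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_cutoff(self, published_truncated_fit):
        thrs = [icc_threshold_for_posterior(published_truncated_fit, c) for c in (0.01, 0.1, 0.5, 0.9)]
        assert all(np.diff(thrs) > 0)

    def test_degenerate_fit_raises(self):
        fit = _fit("censored", p=0.0)  # posterior identically 1
        with pytest.raises(ValueError, match="never crosses"):
            icc_threshold_for_posterior(fit, 0.5)


class TestClassification:
    def test_zero_low_high_partition(self, published_truncated_fit):
        import pandas as pd

        icc = pd.DataFrame({"icc": [0.0, 0.10, 0.37, 0.38, 0.80, 0.0]},
                           index=[f"cg{i}" for i in range(6)])
        out = classify_sites(icc, published_truncated_fit, pi_cutoff=0.01)
        assert out.loc["cg0", "cluster"] == "zero"
        assert out.loc["cg5", "cluster"] == "zero"
        assert out.loc["cg1", "cluster"] == "low"     # density ratio ~ e^-16
        assert out.loc["cg2", "cluster"] == "low"     # just below the 0.374 threshold
        assert out.loc["cg3", "cluster"] == "high"
        assert out.loc["cg4", "cluster"] == "high"
        counts = out.cluster.value_counts()
        assert counts.sum() == 6

    def test_boundary_assigned_high(self):
        # symmetric fit: posterior at the midpoint is exactly 0.5
        fit = _fit("censored", p=0.5, mu1=0.3, sigma1=0.1, mu2=0.7, sigma2=0.1)
        assert posterior_high(fit, 0.5) >= 0.5  # symmetric point, tied up to rounding
        import pandas as pd

        icc = pd.DataFrame({"icc": [0.5]}, index=["cg0"])
        out = classify_sites(icc, fit, pi_cutoff=0.5)
        assert out.loc["cg0", "cluster"] == "high"


class TestModelComparison:
    def test_tie_goes_to_truncated(self):
        a = _fit("censored", loglik=-100.0, n_obs=500)
        b = _fit("truncated", loglik=-100.0, n_obs=500)
        winner, diff = compare_models(a, b)
        assert winner.model_kind == "truncated" and diff == 0.0

    def test_different_sizes_rejected(self):
        with pytest.raises(ValueError, match="different data sizes"):
            compare_models(_fit(n_obs=100), _fit("truncated", n_obs=200))

    def test_zero_inflated_data_prefers_truncated(self):
        x = simulate_icc_sample(0.25, 0.5, 0.3, 0.1, 0.7, 0.1, n=5000, seed=7)
        fc = fit_censored_mixture(x, seed=0)
        ft = fit_truncated_mixture(x, seed=0)
        winner, diff = compare_models(fc, ft)
        assert winner.model_kind == "truncated"
        assert diff > 0

    def test_censored_data_keeps_censored_competitive(self):
        """On data generated by the censored model itself, the censored fit's
        log likelihood is within sampling error of the winner."""
        rng = np.random.default_rng(8)
        n = 5000
        comp = rng.random(n) < 0.55
        x = np.clip(np.where(comp, rng.normal(0.15, 0.14, n), rng.normal(0.67, 0.14, n)), 0, 1)
        fc = fit_censored_mixture(x, seed=0)
        ft = fit_truncated_mixture(x, seed=0)
        winner, diff = compare_models(fc, ft)
        assert fc.loglik >= winner.loglik - 0.005 * abs(winner.loglik)


def _direct_max_censored(x: np.ndarray, seed: int = 0) -> float:
    """Independent oracle: multi-start quasi-Newton maximization of the
    censored-mixture likelihood over unconstrained parameters."""

    def negll(theta):
        p = 1 / (1 + math.exp(-theta[0]))
        fit = _fit(p=p, mu1=theta[1], sigma1=math.exp(theta[2]),
                   mu2=theta[3], sigma2=math.exp(theta[4]))
        return -censored_mixture_loglik(fit, x)

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(8):
        theta0 = np.array([
            rng.normal(0, 1),
            rng.uniform(0.0, 0.4),
            math.log(rng.uniform(0.05, 0.3)),
            rng.uniform(0.4, 0.9),
            math.log(rng.uniform(0.05, 0.3)),
        ])
        res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10})
        best = min(best, res.fun)
    return -best


def test_em_matches_direct_maximization():
    """EM reaches the same maximized likelihood as direct numerical
    optimization of the censored-mixture objective (n = 500)."""
    rng = np.random.default_rng(10)
    n = 500
    comp = rng.random(n) < 0.5
    x = np.clip(np.where(comp, rng.normal(0.12, 0.12, n), rng.normal(0.7, 0.12, n)), 0, 1)
    fit = fit_censored_mixture(x, seed=0)
    oracle = _direct_max_censored(x)
    assert fit.loglik >= oracle - 1e-4
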