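import numpy as np
import pytest
from scipy.integrate import quad

from rempropensity.gmm import (
    GmmParams,
    em_fit,
    fit_with_restarts,
    gmm_density,
    ks_statistic,
    lilliefors_p,
    mixture_cdf,
    _sample_mixture,
)

TRUE = GmmParams(k_l=0.75, mu_l=6.8, sigma_l=0.55, mu_s=4.7, sigma_s=0.45)


def _quantile(params, q, lo=-10, hi=20):
    # bisection on the mixture CDF (independent of the fitting code path)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mixture_cdf(params, mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestDensity:
    @pytest.mark.parametrize(
        "params",
        [
            TRUE,
            GmmParams(0.3, 2.0, 0.2, -1.0, 1.5),
            GmmParams(0.95, 0.0, 1.0, -0.5, 0.1),
        ],
    )
    def test_integrates_to_one(self, params):
        total, err = quad(
            lambda x: gmm_density(params, x), -30, 40, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_weight_is_single_normal(self):
        from scipy.stats import norm

        p = GmmParams(1.0, 2.0, 0.5, 0.0, 1.0)
        x = np.linspace(-2, 6, 50)
        assert np.allclose(gmm_density(p, x), norm.pdf(x, 2.0, 0.5))

    def test_identical_components_is_single_normal(self):
        from scipy.stats import norm

        p = GmmParams(0.5, 1.0, 0.7, 1.0, 0.7)
        x = np.linspace(-3, 5, 50)
        assert np.allclose(gmm_density(p, x), norm.pdf(x, 1.0, 0.7))


class TestEmFit:
    def test_loglik_monotone(self):
        rng = np.random.default_rng(0)
        x = _sample_mixture(TRUE, 1500, rng)
        init = GmmParams(0.5, 6.0, 1.0, 5.0, 1.0)
        _, _, _, trace = em_fit(x, init, track_loglik=True)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_recovers_separated_mixture(self):
        rng = np.random.default_rng(3)
        x = _sample_mixture(TRUE, 5000, rng)
        fit = fit_with_restarts(x, seed=4)
        p = fit.params
        assert p.mu_l == pytest.approx(TRUE.mu_l, abs=0.1)
        assert p.mu_s == pytest.approx(TRUE.mu_s, abs=0.1)
        assert p.sigma_l == pytest.approx(TRUE.sigma_l, abs=0.1)
        assert p.sigma_s == pytest.approx(TRUE.sigma_s, abs=0.1)
        assert p.k_l == pytest.approx(TRUE.k_l, abs=0.05)
        assert fit.converged

    def test_matches_sklearn_oracle(self):
        # independent EM implementation as cross-check on one sample
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(11)
        x = _sample_mixture(TRUE, 4000, rng)
        ours = fit_with_restarts(x, seed=12).params
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(
            x.reshape(-1, 1)
        )
        order = np.argsort(gm.means_.ravel())[::-1]
        mu_l, mu_s = gm.means_.ravel()[order]
        s_l, s_s = np.sqrt(gm.covariances_.ravel()[order])
        k_l = gm.weights_.ravel()[order][0]
        assert ours.mu_l == pytest.approx(mu_l, abs=0.05)
        assert ours.mu_s == pytest.approx(mu_s, abs=0.05)
        assert ours.sigma_l == pytest.approx(s_l, abs=0.05)
        assert ours.sigma_s == pytest.approx(s_s, abs=0.05)
        assert ours.k_l == pytest.approx(k_l, abs=0.03)

    def test_single_normal_data_flagged_degenerate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 0.5, 2000)
        fit = fit_with_restarts(x, seed=6)
        p = fit.params
        degenerate = (
            p.k_l > 0.9 or p.k_l < 0.1 or abs(p.mu_l - p.mu_s) < 0.25
        )
        assert degenerate

    def test_determinism(self):
        rng = np.random.default_rng(7)
        x = _sample_mixture(TRUE, 800, rng)
        a = fit_with_restarts(x, seed=99)
        b = fit_with_restarts(x, seed=99)
        assert a.params == b.params and a.ks_stat == b.ks_stat

    def test_relabelling_invariance(self):
        a = GmmParams.canonical(0.3, 1.0, 0.5, 4.0, 0.2)
        b = GmmParams.canonical(0.7, 4.0, 0.2, 1.0, 0.5)
        assert a == b and a.mu_l > a.mu_s

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0, 2.0]), TRUE)


class TestKsStatistic:
    def test_single_point_at_median(self):
        med = _quantile(TRUE, 0.5)
        assert ks_statistic(np.array([med]), TRUE) == pytest.approx(0.5, abs=1e-9)

    def test_quantile_sample_statistic_shrinks(self):
        d = []
        for n in (50, 500):
            q = (np.arange(1, n + 1)) / (n + 1)
            sample = np.array([_quantile(TRUE, qi) for qi in q])
            d.append(ks_statistic(sample, TRUE))
        assert d[1] < d[0] < 0.05

    def test_shifted_sample_detected(self):
        rng = np.random.default_rng(8)
        shifted = GmmParams(
            TRUE.k_l, TRUE.mu_l + 2, TRUE.sigma_l, TRUE.mu_s + 2, TRUE.sigma_s
        )
        x = _sample_mixture(shifted, 1000, rng)
        assert ks_statistic(x, TRUE) > 0.3


class TestLilliefors:
    def test_p_in_unit_interval_and_well_specified_data_not_rejected(self):
        rng = np.random.default_rng(9)
        x = _sample_mixture(TRUE, 400, rng)
        p, fit = lilliefors_p(x, n_mc=50, seed=10, fast_init=TRUE)
        assert 0.0 <= p <= 1.0
        assert fit.ks_p == p

    def test_grossly_misspecified_data_rejected(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(2.0, 9.0, 1000)
        init = GmmParams(0.5, 7.0, 1.0, 4.0, 1.0)
        p, _ = lilliefors_p(x, n_mc=100, seed=14, fast_init=init)
        assert p < 0.05
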