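"""Continuous-model distances: quadrature, smoothing, invariance, Fisher."""

import numpy as np
import pytest
from scipy import stats

from nqdist import (
    Grid,
    KernelDensityEstimate,
    Normal,
    NormalMixture,
    Poisson,
    default_grid,
    fisher_local_tv,
    kl_sample_sample,
    model_from_spec,
    silverman_bandwidth,
    total_variation,
    tv_density_density,
    tv_invariance_check,
    tv_sample_model,
)


def equal_variance_normal_tv(delta_mu, sigma=1.0):
    """Closed form: TV(N(a, s^2), N(b, s^2)) = 2 Phi(|a-b| / 2s) - 1."""
    return 2.0 * stats.norm.cdf(abs(delta_mu) / (2.0 * sigma)) - 1.0


class TestModels:
    def test_normal_pdf_integrates(self):
        m = Normal(1.0, 2.0)
        g = Grid(-20, 22, 4001).points
        assert np.trapezoid(m.pdf(g), g) == pytest.approx(1.0, abs=1e-6)

    def test_sampling_reproducible(self):
        m = Normal()
        assert np.array_equal(m.sample(10, 42), m.sample(10, 42))
        mix = NormalMixture([0.5, 0.5], [0, 5], [1, 1])
        assert np.array_equal(mix.sample(10, 7), mix.sample(10, 7))

    def test_mixture_pdf_and_cdf(self):
        mix = NormalMixture([0.3, 0.7], [0.0, 5.0], [1.0, 2.0])
        x = np.array([-1.0, 0.0, 4.0])
        expected = 0.3 * stats.norm.pdf(x) + 0.7 * stats.norm.pdf(x, 5, 2)
        assert np.allclose(mix.pdf(x), expected)
        assert mix.cdf(20.0) == pytest.approx(1.0, abs=1e-8)

    def test_score_matches_numerical_derivative(self):
        m = Normal(0.5, 1.5)
        x = np.array([-1.0, 0.3, 2.0])
        eps = 1e-6
        d_mu = (Normal(0.5 + eps, 1.5).log_pdf(x) - m.log_pdf(x)) / eps
        assert np.allclose(m.score(x)[0], d_mu, atol=1e-4)
        lam = Poisson(2.0)
        k = np.array([0.0, 1.0, 5.0])
        d_lam = (Poisson(2.0 + eps).log_pdf(k) - lam.log_pdf(k)) / eps
        assert np.allclose(lam.score(k), d_lam, atol=1e-4)

    def test_model_from_spec_round_trip(self):
        m = model_from_spec({"family": "normal", "theta": [0, 1]})
        assert isinstance(m, Normal) and m.theta == (0.0, 1.0)
        with pytest.raises(ValueError, match="unknown family"):
            model_from_spec({"family": "cauchy", "theta": [0]})
        with pytest.raises(ValueError, match="malformed"):
            model_from_spec({"theta": [0]})


class TestKernelDensityEstimate:
    def test_integrates_to_one_and_positive(self, rng):
        x = rng.normal(2.0, 1.5, 400)
        kde = KernelDensityEstimate(x)
        h = kde.bandwidth
        g = np.linspace(x.min() - 5 * h, x.max() + 5 * h, 4001)
        vals = kde.pdf(g)
        assert np.all(vals > 0)
        assert np.trapezoid(vals, g) == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_kernel_average(self, rng):
        x = rng.normal(0, 1, 50)
        kde = KernelDensityEstimate(x, bandwidth=0.3)
        pts = np.array([-0.5, 0.0, 1.2])
        direct = stats.norm.pdf(pts[:, None], x[None, :], 0.3).mean(axis=1)
        assert np.allclose(kde.pdf(pts), direct)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            KernelDensityEstimate(np.ones(10))

    def test_silverman_rule_value(self):
        x = np.arange(100, dtype=float)
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.349) * 100 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected)


class TestTvDensityDensity:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0, 5.0])
    def test_matches_equal_variance_closed_form(self, mu):
        grid = default_grid(model=Normal(mu / 2, 1), n_points=8192)
        grid = Grid(grid.lo - mu, grid.hi + mu, 8192)
        res = tv_density_density(Normal(0, 1), Normal(mu, 1), grid)
        assert res.value == pytest.approx(equal_variance_normal_tv(mu),
                                          abs=1e-6)

    def test_identical_densities(self):
        grid = default_grid(model=Normal(), n_points=2048)
        assert tv_density_density(Normal(), Normal(), grid).value == \
            pytest.approx(0.0, abs=1e-12)

    def test_mixture_against_base_analytic_reduction(self):
        # 0.5 N(0,1) + 0.5 N(5,1) vs N(0,1): TV = 0.5 * TV(N(0,1), N(5,1))
        mix = NormalMixture([0.5, 0.5], [0.0, 5.0], [1.0, 1.0])
        grid = Grid(-10, 15, 8192)
        expected = 0.5 * equal_variance_normal_tv(5.0)
        assert tv_density_density(mix, Normal(), grid).value == \
            pytest.approx(expected, abs=1e-6)

    def test_coverage_warning_on_short_grid(self):
        res = tv_density_density(Normal(), Normal(3, 1), Grid(-2, 2, 512))
        assert "coverage_warning" in res.meta


class TestTvSampleModel:
    def test_decreasing_on_nested_samples_from_the_model(self, rng):
        m = Normal()
        x = m.sample(5000, rng)
        vals = [tv_sample_model(x[:n], m).value for n in (200, 1000, 5000)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.05

    def test_sample_order_invariant(self, rng):
        m = Normal()
        x = m.sample(300, rng)
        a = tv_sample_model(x, m).value
        b = tv_sample_model(x[::-1].copy(), m).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_empirical_atoms_without_smoothing_have_tv_one(self, rng):
        # Discretization robustness: the TV between a discrete empirical
        # measure and a continuous density is the maximum possible, 1.
        # Shrinking cells around the atoms carry all empirical mass but
        # vanishing model mass; the leftover model mass sits in a cell with
        # zero data.
        x = np.sort(rng.normal(0, 1, 40))
        m = Normal()
        for width in (1e-2, 1e-5):
            cell_mass = m.cdf(x + width / 2) - m.cdf(x - width / 2)
            tau = np.append(np.full(x.size, 1.0 / x.size), 0.0)
            model = np.append(cell_mass, 1.0 - cell_mass.sum())
            v = total_variation(tau, model).value
            assert v > 1.0 - x.size * width
        assert v > 0.999


class TestKlSampleSample:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(0, 1, 200)
        assert kl_sample_sample(x, x).value == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 150)
            y = rng.normal(rng.uniform(-1, 1), 1, 150)
            assert kl_sample_sample(x, y).value >= -1e-12

    def test_disjoint_two_bin_toy(self):
        # n points of x in the left bin, n of y in the right bin; with
        # additive smoothing alpha the frequencies are exact binomials.
        n, alpha = 4, 0.5
        x = np.full(n, 0.0) + [0.0, 0.1, 0.2, 0.3]
        y = np.full(n, 10.0) + [0.0, 0.1, 0.2, 0.3]
        p = np.array([n + alpha, alpha]) / (n + 2 * alpha)
        q = np.array([alpha, n + alpha]) / (n + 2 * alpha)
        expected = float(np.sum(q * np.log(q / p)))
        got = kl_sample_sample(x, y, n_bins=2, alpha=alpha).value
        assert got == pytest.approx(expected)
        assert got > 0

    def test_bin_validation(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="bins"):
            kl_sample_sample(x, x, n_bins=1)


class TestInvarianceUnderTransformation:
    def test_affine_transform_preserves_tv(self, rng):
        x = rng.normal(1, 1, 400)
        orig, trans = tv_invariance_check(
            x, Normal(1, 1),
            forward=lambda t: 2 * t + 1,
            inverse=lambda y: (y - 1) / 2,
            inverse_deriv=lambda y: np.full_like(y, 0.5))
        assert trans.value == pytest.approx(orig.value, abs=1e-6)

    def test_exp_transform_preserves_tv(self, rng):
        x = rng.normal(0, 1, 400)
        orig, trans = tv_invariance_check(
            x, Normal(0.5, 1),
            forward=np.exp, inverse=np.log, inverse_deriv=lambda y: 1.0 / y)
        assert trans.value == pytest.approx(orig.value, abs=1e-4)

    def test_identity_transform_exact(self, rng):
        x = rng.normal(0, 1, 200)
        orig, trans = tv_invariance_check(
            x, Normal(), forward=lambda t: t, inverse=lambda y: y,
            inverse_deriv=lambda y: np.ones_like(y))
        assert trans.value == pytest.approx(orig.value, abs=1e-12)

    def test_non_monotone_transform_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        with pytest.raises(ValueError, match="monotone"):
            tv_invariance_check(x, Normal(), forward=np.square,
                                inverse=np.sqrt,
                                inverse_deriv=lambda y: 0.5 / np.sqrt(y))


class TestFisherLocalTv:
    def test_zero_at_theta0(self):
        res = fisher_local_tv(lambda mu, s: Normal(mu, s), [0, 1], [0, 1],
                              n=100, reps=10, seed=0)
        assert res.value == 0.0

    @pytest.mark.parametrize("make,theta0,dtheta,info", [
        (lambda mu: Normal(mu, 1.0), 1.0, 0.002, 1.0),
        (lambda lam: Poisson(lam), 1.0, 0.002, 1.0),
    ])
    def test_local_limit_normal_and_poisson(self, make, theta0, dtheta, info):
        # In the local regime sqrt(n) * dtheta small, the scaled product-
        # measure TV approaches |dtheta| * sqrt(I(theta0) / (2 pi)).
        n = 10_000
        res = fisher_local_tv(make, [theta0], [theta0 + dtheta], n=n,
                              reps=1500, seed=11)
        limit = dtheta * np.sqrt(info / (2 * np.pi))
        assert res.value == pytest.approx(limit, abs=3 * res.meta["se"])
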