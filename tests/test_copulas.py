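"""Copula families: distributional identities, densities, sampling, rank correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from dosecopula.copulas import (
    FAMILY_ORDER,
    ClaytonCopula,
    FrankCopula,
    GaussianCopula,
    GumbelCopula,
    StudentTCopula,
    debye,
    kendall_tau_quadrature,
    make_copula,
    spearman_rho_quadrature,
)

# parameters on the scale of the published per-indication fits
FITTED_SCALE = [
    ClaytonCopula(6.9819),
    FrankCopula(16.7833),
    GumbelCopula(4.2334),
    GaussianCopula(0.8646),
    StudentTCopula(0.9789, 6.0473),
]

MODERATE = [
    ClaytonCopula(2.0),
    FrankCopula(5.0),
    GumbelCopula(1.5),
    GaussianCopula(0.5),
    StudentTCopula(0.5, 5.0),
]


def _gl_tensor(f, n=120):
    x, w = np.polynomial.legendre.leggauss(n)
    x = 0.5 * (x + 1)
    w = 0.5 * w
    U, V = np.meshgrid(x, x, indexing="ij")
    return float(np.sum(f(U, V) * np.outer(w, w)))


class TestCDF:
    @pytest.mark.parametrize("model", FITTED_SCALE, ids=lambda m: m.family)
    def test_uniform_margins_and_groundedness(self, model):
        u = np.array([0.1, 0.35, 0.8, 0.99])
        np.testing.assert_allclose(model.cdf(u, np.ones_like(u)), u, atol=1e-9)
        np.testing.assert_allclose(model.cdf(np.ones_like(u), u), u, atol=1e-9)
        np.testing.assert_allclose(model.cdf(u, np.zeros_like(u)), 0.0, atol=1e-9)
        np.testing.assert_allclose(model.cdf(np.zeros_like(u), u), 0.0, atol=1e-9)

    def test_clayton_direct_substitution(self):
        # (0.5^-2 + 0.5^-2 - 1)^(-1/2) = 7^(-1/2)
        assert ClaytonCopula(2.0).cdf(0.5, 0.5) == pytest.approx(7 ** -0.5, abs=1e-12)

    def test_gumbel_matches_monte_carlo_quadrant_probability(self):
        model = GumbelCopula(4.2334)
        n = 10**6
        s = model.sample(n, seed=99)
        p_hat = np.mean((s[:, 0] <= 0.3) & (s[:, 1] <= 0.7))
        sd = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(model.cdf(0.3, 0.7) - p_hat) < 3 * sd

    @pytest.mark.parametrize("model", FITTED_SCALE, ids=lambda m: m.family)
    def test_two_increasing_on_grid(self, model):
        g = np.linspace(0.0, 1.0, 21)
        C = model.cdf(g[:, None], g[None, :])
        rect = C[1:, 1:] - C[1:, :-1] - C[:-1, 1:] + C[:-1, :-1]
        assert rect.min() >= -1e-9

    def test_elliptical_cdf_against_scipy_quadrant_probability(self):
        # independent implementation: scipy's multivariate QMC integrator
        rho, nu = 0.9179, 2.6696
        model = StudentTCopula(rho, nu)
        x = sps.t.ppf([0.3, 0.7], nu)
        ref = sps.multivariate_t(shape=[[1, rho], [rho, 1]], df=nu).cdf(x)
        assert model.cdf(0.3, 0.7) == pytest.approx(ref, abs=5e-4)
        gref = sps.multivariate_normal(cov=[[1, 0.8646], [0.8646, 1]]).cdf(sps.norm.ppf([0.3, 0.7]))
        assert GaussianCopula(0.8646).cdf(0.3, 0.7) == pytest.approx(gref, abs=1e-9)


class TestPDF:
    def test_frank_independence_limit_density_is_one(self):
        u, v = np.meshgrid(np.linspace(0.05, 0.95, 7), np.linspace(0.05, 0.95, 7))
        np.testing.assert_allclose(FrankCopula(0.0).pdf(u, v), 1.0)
        np.testing.assert_allclose(FrankCopula(1e-8).pdf(u, v), 1.0, atol=1e-6)

    @pytest.mark.parametrize("model", MODERATE, ids=lambda m: m.family)
    def test_density_normalises_to_one(self, model):
        assert _gl_tensor(model.pdf) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize(
        "model", [ClaytonCopula(2.0), FrankCopula(5.0), GumbelCopula(2.5)], ids=lambda m: m.family
    )
    def test_density_is_mixed_derivative_of_cdf(self, model):
        h = 1e-4
        u, v = 0.5, 0.45
        fd = (
            model.cdf(u + h, v + h)
            - model.cdf(u + h, v - h)
            - model.cdf(u - h, v + h)
            + model.cdf(u - h, v - h)
        ) / (4 * h * h)
        assert model.pdf(u, v) == pytest.approx(fd, abs=1e-4)

    @pytest.mark.parametrize(
        "model", [GaussianCopula(0.8646), StudentTCopula(0.9, 4.0)], ids=lambda m: m.family
    )
    def test_elliptical_density_is_mixed_derivative_of_cdf(self, model):
        h = 1e-3
        fd = (
            model.cdf(0.5 + h, 0.45 + h)
            - model.cdf(0.5 + h, 0.45 - h)
            - model.cdf(0.5 - h, 0.45 + h)
            + model.cdf(0.5 - h, 0.45 - h)
        ) / (4 * h * h)
        assert model.pdf(0.5, 0.45) == pytest.approx(fd, rel=1e-3)


class TestSampling:
    @pytest.mark.parametrize("model", FITTED_SCALE, ids=lambda m: m.family)
    def test_margins_uniform(self, model):
        s = model.sample(10_000, seed=11)
        assert sps.kstest(s[:, 0], "uniform").pvalue > 0.01
        assert sps.kstest(s[:, 1], "uniform").pvalue > 0.01

    @pytest.mark.parametrize("model", FITTED_SCALE, ids=lambda m: m.family)
    def test_sample_tau_matches_model_tau(self, model):
        s = model.sample(100_000, seed=5)
        tau_hat = sps.kendalltau(s[:, 0], s[:, 1]).statistic
        assert tau_hat == pytest.approx(model.kendall_tau(), abs=0.01)

    def test_independence_gives_zero_tau(self):
        s = GaussianCopula(1e-12).sample(10_000, seed=3)
        assert abs(sps.kendalltau(s[:, 0], s[:, 1]).statistic) < 0.03

    def test_reproducible_given_seed(self):
        m = ClaytonCopula(3.0)
        np.testing.assert_array_equal(m.sample(100, seed=8), m.sample(100, seed=8))


class TestDependenceMeasures:
    @pytest.mark.parametrize(
        "model, tau",
        [
            (ClaytonCopula(6.9819), 0.7773),
            (GumbelCopula(4.2334), 0.7638),
            (FrankCopula(16.7833), 0.7850),
            (GumbelCopula(1.0), 0.0),
        ],
    )
    def test_kendall_closed_forms(self, model, tau):
        assert round(model.kendall_tau(), 4) == pytest.approx(tau, abs=5e-5)

    @pytest.mark.parametrize(
        "model, rho_s",
        [
            (GaussianCopula(0.8646), 0.8538),
            (FrankCopula(16.7833), 0.9421),
        ],
    )
    def test_spearman_closed_forms(self, model, rho_s):
        assert round(model.spearman_rho(), 4) == pytest.approx(rho_s, abs=5e-5)

    def test_frank_independence_limits(self):
        assert FrankCopula(0.0).kendall_tau() == 0.0
        assert FrankCopula(0.0).spearman_rho() == 0.0

    def test_tau_strictly_increasing_in_parameter(self):
        for fam, grid in [
            ("Clayton", [0.5, 1, 2, 4, 8]),
            ("Gumbel", [1.1, 1.5, 2, 4, 8]),
            ("Frank", [0.5, 2, 5, 10, 20]),
        ]:
            taus = [make_copula(fam, alpha=a).kendall_tau() for a in grid]
            assert np.all(np.diff(taus) > 0)
        for fam in ("Gaussian", "StudentT"):
            kw = {"nu": 5.0} if fam == "StudentT" else {}
            taus = [make_copula(fam, rho=r, **kw).kendall_tau() for r in [0.1, 0.3, 0.6, 0.9]]
            assert np.all(np.diff(taus) > 0)

    def test_tau_and_spearman_share_sign_and_bounds(self):
        for model in FITTED_SCALE:
            tau, rho_s = model.kendall_tau(), model.spearman_rho()
            assert -1 <= tau <= 1 and -1 <= rho_s <= 1
            assert np.sign(tau) == np.sign(rho_s)

    def test_student_t_spearman_differs_from_gaussian_closed_form(self):
        # at low nu the arcsin(rho/2) law is not exact
        t_rho_s = StudentTCopula(0.9179, 2.6696).spearman_rho()
        gauss_law = 6 / np.pi * np.arcsin(0.9179 / 2)
        assert abs(t_rho_s - gauss_law) > 1e-3

    def test_quadrature_matches_closed_forms_spot_checks(self):
        m = ClaytonCopula(2.0)
        assert kendall_tau_quadrature(m) == pytest.approx(m.kendall_tau(), abs=1e-4)
        g = GaussianCopula(0.87)
        assert spearman_rho_quadrature(g) == pytest.approx(g.spearman_rho(), abs=1e-4)


class TestDebye:
    def test_small_x_limit(self):
        assert debye(1, 1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_large_x_tail(self):
        # D1(x) -> pi^2/(6x) - ... ; at x=50 the exponential remainder is negligible
        assert debye(1, 50.0) == pytest.approx(np.pi**2 / 6 / 50, rel=1e-6)

    def test_consistency_with_frank_tau(self):
        a = 16.7833
        tau = 1 - 4 / a * (1 - debye(1, a))
        assert round(tau, 4) == 0.7850

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            debye(1, bad)


class TestValidation:
    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: ClaytonCopula(0.0),
            lambda: ClaytonCopula(-1.0),
            lambda: GumbelCopula(0.9),
            lambda: GaussianCopula(1.0),
            lambda: GaussianCopula(-1.5),
            lambda: StudentTCopula(0.5, 0.5),
            lambda: StudentTCopula(1.2, 5.0),
        ],
    )
    def test_invalid_parameters_rejected(self, ctor):
        with pytest.raises(ValueError):
            ctor()

    def test_family_registry(self):
        assert set(FAMILY_ORDER) == {"Clayton", "Frank", "Gumbel", "Gaussian", "StudentT"}
        with pytest.raises(ValueError):
            make_copula("Plackett", alpha=2.0)

    def test_high_nu_delegates_to_gaussian(self):
        t = StudentTCopula(0.7, 150.0)
        g = GaussianCopula(0.7)
        assert t.cdf(0.3, 0.6) == pytest.approx(g.cdf(0.3, 0.6), abs=1e-12)
        assert t.spearman_rho() == pytest.approx(g.spearman_rho(), abs=1e-12)
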