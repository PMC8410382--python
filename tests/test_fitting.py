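"""Empirical copula, pseudo-maximum-likelihood estimation, distance-based selection."""

import numpy as np
import pytest
from scipy import stats as sps

from dosecopula.copulas import (
    ClaytonCopula,
    FrankCopula,
    GaussianCopula,
    StudentTCopula,
    make_copula,
)
from dosecopula.fitting import (
    FitError,
    empirical_copula,
    fit_family,
    select_best,
    squared_euclidean_distance,
    tau_inversion,
)
from dosecopula.marginals import PseudoObservations, to_pseudo_observations
from conftest import rank_pseudo


def _uniform_pseudo(n, seed):
    rng = np.random.default_rng(seed)
    lo = 1 / (2 * n)
    return PseudoObservations(
        u=np.clip(rng.uniform(size=n), lo, 1 - lo),
        v=np.clip(rng.uniform(size=n), lo, 1 - lo),
        method="rank",
    )


class TestEmpiricalCopula:
    def test_comonotone_counting(self):
        g = np.array([0.2, 0.4, 0.6, 0.8] * 3)  # n >= 10
        emp = empirical_copula(PseudoObservations(u=g, v=g, method="rank"))
        assert emp(0.5, 0.5) == pytest.approx(0.5)

    def test_everything_counted_at_corner(self, rng):
        emp = empirical_copula(_uniform_pseudo(50, 0))
        assert emp(1.0, 1.0) == 1.0

    def test_independent_sample_quarter_mass(self):
        emp = empirical_copula(_uniform_pseudo(10_000, 1))
        assert emp(0.5, 0.5) == pytest.approx(0.25, abs=0.02)

    def test_minimum_size_enforced(self):
        g = np.linspace(0.1, 0.9, 5)
        with pytest.raises(ValueError):
            empirical_copula(PseudoObservations(u=g, v=g, method="rank"))


class TestTauInversion:
    @pytest.mark.parametrize(
        "family, tau, expected",
        [
            ("Clayton", 0.7773, 6.9819),
            ("Gumbel", 0.7638, 4.2334),
            ("Frank", 0.7850, 16.7833),
        ],
    )
    def test_inverts_published_closed_forms(self, family, tau, expected):
        assert tau_inversion(family, tau)["alpha"] == pytest.approx(expected, abs=0.01)

    def test_elliptical_sine_relation(self):
        assert tau_inversion("Gaussian", 0.5)["rho"] == pytest.approx(np.sin(np.pi / 4))


class TestFitFamily:
    def test_clayton_recovery_matches_tau_inversion_oracle(self):
        truth = ClaytonCopula(3.0)
        s = truth.sample(2000, seed=21)
        ps = rank_pseudo(s)
        fitted = fit_family("Clayton", ps)
        assert fitted.alpha == pytest.approx(3.0, abs=0.3)
        # independent moment estimate from the same sample
        tau_hat = sps.kendalltau(ps.u, ps.v).statistic
        assert fitted.alpha == pytest.approx(tau_inversion("Clayton", tau_hat)["alpha"], rel=0.15)

    def test_gaussian_recovery_matches_normal_scores_oracle(self):
        truth = GaussianCopula(0.95)
        s = truth.sample(2000, seed=22)
        ps = rank_pseudo(s)
        fitted = fit_family("Gaussian", ps)
        assert fitted.rho == pytest.approx(0.95, abs=0.015)
        scores_corr = np.corrcoef(sps.norm.ppf(ps.u), sps.norm.ppf(ps.v))[0, 1]
        assert fitted.rho == pytest.approx(scores_corr, abs=0.01)

    def test_student_t_joint_estimation(self):
        truth = StudentTCopula(0.95, 4.0)
        ps = rank_pseudo(truth.sample(2000, seed=23))
        fitted = fit_family("StudentT", ps)
        assert fitted.rho == pytest.approx(0.95, abs=0.02)
        assert fitted.nu == pytest.approx(4.0, abs=2.0)

    def test_comonotone_degenerate_data_flagged(self):
        g = np.linspace(0.02, 0.98, 200)
        ps = PseudoObservations(u=g, v=g, method="rank")
        with pytest.raises(FitError) as exc_info:
            fit_family("Gaussian", ps)
        assert exc_info.value.best is not None  # best iterate carried

    def test_deterministic(self):
        ps = rank_pseudo(FrankCopula(10.0).sample(500, seed=4))
        a = fit_family("Frank", ps)
        b = fit_family("Frank", ps)
        assert a.params == b.params


class TestSquaredEuclideanDistance:
    def test_zero_when_model_matches_empirical(self):
        ps = _uniform_pseudo(100, 5)
        emp = empirical_copula(ps)

        class Mimic:
            def cdf(self, u, v):
                return emp(u, v)

        assert squared_euclidean_distance(Mimic(), emp) == 0.0

    def test_permutation_invariant(self):
        ps = _uniform_pseudo(200, 6)
        emp = empirical_copula(ps)
        model = FrankCopula(2.0)
        d1 = squared_euclidean_distance(model, emp)
        perm = np.random.default_rng(0).permutation(200)
        emp2 = empirical_copula(PseudoObservations(u=ps.u[perm], v=ps.v[perm], method="rank"))
        assert squared_euclidean_distance(model, emp2) == pytest.approx(d1, rel=1e-12)

    def test_independence_model_beats_wrong_strong_dependence(self):
        ps = _uniform_pseudo(500, 7)
        emp = empirical_copula(ps)
        near_independence = FrankCopula(1e-4)
        assert squared_euclidean_distance(near_independence, emp) < squared_euclidean_distance(
            ClaytonCopula(7.0), emp
        )


class TestSelectBest:
    def test_best_attains_minimum_distance(self):
        ps = rank_pseudo(GaussianCopula(0.9).sample(300, seed=9))
        report = select_best(ps)
        converged = [r for r in report.results if r.converged]
        assert report.best.distance == min(r.distance for r in converged)
        assert len(report.results) == 5

    def test_report_tau_is_model_implied(self):
        ps = rank_pseudo(ClaytonCopula(4.0).sample(300, seed=10))
        report = select_best(ps, families=("Clayton",))
        row = report.results[0]
        assert row.tau == row.model.kendall_tau()  # same code path, no re-estimation

    def test_student_t_selected_on_t_data(self):
        wins = top2 = 0
        n_seeds = 20
        truth = StudentTCopula(0.95, 4.0)
        for seed in range(n_seeds):
            ps = rank_pseudo(truth.sample(1000, seed=seed))
            ranked = [r.family for r in select_best(ps).ranked()]
            wins += ranked[0] == "StudentT"
            top2 += "StudentT" in ranked[:2]
        assert wins >= 0.6 * n_seeds
        assert top2 >= 0.9 * n_seeds

    def test_clayton_top_two_on_clayton_data(self):
        top2 = 0
        n_seeds = 20
        truth = ClaytonCopula(6.0)
        for seed in range(n_seeds):
            ps = rank_pseudo(truth.sample(1000, seed=100 + seed))
            ranked = [r.family for r in select_best(ps).ranked()]
            top2 += "Clayton" in ranked[:2]
        assert top2 >= 0.8 * n_seeds

    def test_distance_of_true_family_shrinks_with_sample_size(self):
        truth = make_copula("Gumbel", alpha=4.0)
        med = {}
        for n in (200, 2000):
            dists = []
            for seed in range(5):
                ps = rank_pseudo(truth.sample(n, seed=200 + seed))
                emp = empirical_copula(ps)
                dists.append(squared_euclidean_distance(truth, emp))
            med[n] = np.median(dists)
        assert med[2000] < med[200]
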