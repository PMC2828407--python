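"""Matrix analytics: growth rate, structure, elasticities, age schedules."""

import numpy as np
import pytest

from stagessm import (
    DemographicRates,
    ObservationRate,
    ValidationError,
    age_specific_fertility,
    age_specific_survivorship,
    age_within_stage,
    build_lefkovitch,
    demography_summary,
    dominant_eigensystem,
    elasticity_matrix,
    posterior_demography,
    reproductive_values,
)
from conftest import random_valid_rates


def power_iteration_oracle(M, tol=1e-13, iters=200_000):
    w = np.ones(M.shape[0]) / M.shape[0]
    lam = 0.0
    for _ in range(iters):
        nxt = M @ w
        lam_new = nxt.sum()
        nxt = nxt / lam_new
        if np.abs(nxt - w).max() < tol and abs(lam_new - lam) < tol:
            return lam_new, nxt
        w, lam = nxt, lam_new
    raise RuntimeError("no convergence")


class TestEigensystem:
    def test_median_growth_rate_rounds_to_reference(self, median_matrix):
        lam, w, v = dominant_eigensystem(median_matrix)
        assert round(lam, 2) == 0.95
        assert lam == pytest.approx(0.95225, abs=1e-4)

    def test_median_stable_structure(self, median_matrix):
        _, w, _ = dominant_eigensystem(median_matrix)
        assert w == pytest.approx([0.2400, 0.2706, 0.4894], abs=5e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_diagonal_matrix_spectral_radius(self):
        lam, w, _ = dominant_eigensystem(np.diag([0.2, 0.4, 0.7]))
        assert lam == pytest.approx(0.7)

    def test_matches_power_iteration_on_random_matrices(self, rng):
        """Eigen decomposition agrees with an independent power-iteration
        oracle, and both eigenvectors satisfy their defining residuals."""
        for rates in random_valid_rates(rng, 200):
            M = np.asarray(build_lefkovitch(rates))
            if M[0, 2] == 0.0:
                continue
            lam, w, v = dominant_eigensystem(M)
            lam_pi, w_pi = power_iteration_oracle(M)
            assert lam == pytest.approx(lam_pi, abs=1e-10)
            np.testing.assert_allclose(w, w_pi, atol=1e-9)
            assert np.abs(M @ w - lam * w).max() < 1e-10
            assert np.abs(v @ M - lam * v).max() < 1e-10

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValidationError):
            dominant_eigensystem(-np.eye(3))


class TestReproductiveValues:
    def test_scaled_to_juvenile_unity(self, median_matrix):
        v = reproductive_values(median_matrix)
        assert v[0] == 1.0

    def test_median_values_and_analytic_solution(self, median_matrix,
                                                 median_rates):
        """v solves vM = lambda*v componentwise: v_S = (lambda - j2)/p1."""
        lam, _, v = dominant_eigensystem(median_matrix)
        r = median_rates
        v_s = (lam - r.j2) / r.p1
        v_a = v_s * (lam - r.s) / r.p2
        assert v[1] == pytest.approx(v_s, abs=1e-10)
        assert v[2] == pytest.approx(v_a, abs=1e-10)
        assert v == pytest.approx([1.0, 1.2537, 1.5888], abs=1e-3)

    def test_scale_invariance(self, median_matrix):
        v1 = reproductive_values(np.asarray(median_matrix))
        v2 = reproductive_values(3.7 * np.asarray(median_matrix))
        np.testing.assert_allclose(v1, v2, atol=1e-10)


class TestElasticities:
    def test_sum_to_one_and_structural_zeros(self, median_matrix):
        E = elasticity_matrix(median_matrix)
        assert E.sum() == pytest.approx(1.0, abs=1e-10)
        assert E[0, 1] == 0.0 and E[1, 2] == 0.0 and E[2, 0] == 0.0

    def test_adult_survival_dominates_at_medians(self, median_matrix):
        E = elasticity_matrix(median_matrix)
        assert E[2, 2] == pytest.approx(0.4333, abs=5e-4)
        assert E[2, 2] == E.max()

    def test_matches_numerical_log_derivative(self, median_matrix):
        """E[i,j] is the central difference of log lambda w.r.t.
        log M[i,j] (step 1e-6)."""
        M = np.asarray(median_matrix)
        E = elasticity_matrix(M)
        h = 1e-6
        for i in range(3):
            for j in range(3):
                if M[i, j] == 0:
                    continue
                up, dn = M.copy(), M.copy()
                up[i, j] *= np.exp(h)
                dn[i, j] *= np.exp(-h)
                d = (np.log(dominant_eigensystem(up)[0])
                     - np.log(dominant_eigensystem(dn)[0])) / (2 * h)
                assert E[i, j] == pytest.approx(d, abs=1e-4)


class TestAgeSchedules:
    def test_survivorship_values_at_medians(self, median_matrix):
        l = age_specific_survivorship(median_matrix, 10)
        assert l[0] == 1.0
        assert l[1] == pytest.approx(0.80, abs=1e-12)
        assert l[2] == pytest.approx(0.664, abs=1e-12)
        # independent matrix-power oracle
        T = median_matrix.T
        for x in range(11):
            assert l[x] == pytest.approx(
                (np.linalg.matrix_power(T, x) @ [1, 0, 0]).sum(), abs=1e-12)
        assert (np.diff(l) <= 0).all()

    def test_zero_transition_matrix(self):
        l = age_specific_survivorship(np.zeros((3, 3)), 5)
        assert l[0] == 1.0 and (l[1:] == 0).all()

    def test_x_max_guard(self, median_matrix):
        with pytest.raises(ValidationError):
            age_specific_survivorship(median_matrix, 0)

    def test_first_year_prepending(self, median_matrix, median_rates):
        base = age_specific_survivorship(median_matrix, 6)
        full = age_specific_survivorship(median_matrix, 6,
                                         include_first_year=True,
                                         j1=median_rates.j1)
        assert full[0] == 1.0
        np.testing.assert_allclose(full[1:], median_rates.j1 * base[:-1])

    def test_fertility_structure_and_oracle(self, median_matrix):
        m = age_specific_fertility(median_matrix, 8)
        assert m[0] == 0.0  # age-1 individuals are all juveniles
        T, F = median_matrix.T, median_matrix.F
        e = np.array([1.0, 0, 0])
        for x in (2, 3, 5):
            cohort = np.linalg.matrix_power(T, x - 1) @ e
            oracle = (F @ cohort).sum() / cohort.sum()
            assert m[x - 1] == pytest.approx(oracle, abs=1e-12)
        # at x = 3 the value is 0.369 * (T^2 e)_A / l(2)
        assert m[2] == pytest.approx(0.369 * 0.252 / 0.664, abs=1e-10)

    def test_zero_fecundity_gives_zero_fertility(self):
        r = DemographicRates(0.45, 0.2, 0.6, 0.42, 0.42, 0.72, 0.0)
        assert (age_specific_fertility(build_lefkovitch(r), 6) == 0).all()

    def test_extinct_cohort_fertility_is_missing_not_zero(self):
        m = age_specific_fertility(np.array([[0.0, 0, 0.3],
                                             [0.0, 0, 0],
                                             [0, 0.0, 0.0]]), 4)
        assert m[0] == 0.0
        assert np.isnan(m[1:]).all()


class TestAgeWithinStage:
    def test_distributions_normalize(self, median_matrix):
        lam = dominant_eigensystem(median_matrix)[0]
        dist = age_within_stage(median_matrix, lam, 50)
        np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-9)

    def test_juvenile_age_one_share(self, median_matrix):
        """~79% of J2 individuals are age 1 at stable growth."""
        lam = dominant_eigensystem(median_matrix)[0]
        dist = age_within_stage(median_matrix, lam, 50)
        # independent truncated geometric series
        T = median_matrix.T
        vec = np.array([1.0, 0, 0])
        terms = []
        for _ in range(50):
            terms.append(vec.copy())
            vec = (T / lam) @ vec
        terms = np.array(terms)
        oracle = terms[0, 0] / terms[:, 0].sum()
        assert dist[0, 0] == pytest.approx(oracle, abs=1e-12)
        assert dist[0, 0] == pytest.approx(0.79, abs=0.005)

    def test_adults_are_older_than_juveniles(self, median_matrix):
        lam = dominant_eigensystem(median_matrix)[0]
        dist = age_within_stage(median_matrix, lam, 50)
        assert dist[2].argmax() > dist[0].argmax()

    def test_tail_guard_requests_larger_x_max(self, median_matrix):
        lam = dominant_eigensystem(median_matrix)[0]
        with pytest.raises(ValidationError, match="x_max"):
            age_within_stage(median_matrix, lam, 5)


class TestPosteriorDemography:
    def test_identical_rows_collapse_intervals(self, median_rates):
        rows = [(median_rates, ObservationRate(0.4))] * 10
        qs = posterior_demography(rows).quantiles()
        assert qs["lam"][0] == pytest.approx(qs["lam"][2])
        assert qs["lam"][1] == pytest.approx(0.95225, abs=1e-4)

    def test_invalid_rows_are_skipped(self, median_rates):
        bad = DemographicRates(0.5, 0.7, 0.7, 0.3, 0.3, 0.5, 0.5,
                               validate=False)
        rows = [(median_rates, ObservationRate(0.4))] * 5 \
            + [(bad, ObservationRate(0.4))]
        demo = posterior_demography(rows)
        assert demo.n_skipped == 1
        assert demo.lam.size == 5

    def test_needs_two_rows(self, median_rates):
        with pytest.raises(ValidationError):
            posterior_demography([(median_rates, ObservationRate(0.4))])

    def test_summary_covers_generating_lambda(self, rng, median_rates):
        """Rows jittered around the medians yield an interval
        containing the median-matrix growth rate."""
        rows = []
        for r in random_valid_rates(rng, 80):
            mix = DemographicRates.from_array(
                0.85 * median_rates.as_array() + 0.15 * r.as_array())
            rows.append((mix, ObservationRate(0.4)))
        qs = posterior_demography(rows).quantiles()
        assert qs["lam"][0] < 0.9522 < qs["lam"][2]


def test_demography_summary_is_self_consistent(median_rates):
    d = demography_summary(median_rates)
    assert round(d.lam, 2) == 0.95
    assert d.E.sum() == pytest.approx(1.0, abs=1e-10)
    assert d.survivorship[0] == 1.0
    assert d.age_within_stage.shape == (3, 50)
    assert d.fertility.shape == (50,)
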