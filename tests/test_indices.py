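import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relmc import indices as I
from relmc import populations as P
from conftest import random_correlation


def equicorrelated(k: int, r: float) -> np.ndarray:
    R = np.full((k, k), r)
    np.fill_diagonal(R, 1.0)
    return R


class TestSampleCorrelation:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        R = I.sample_correlation(X)
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        X = rng.standard_normal((100_000, 6))
        R = I.sample_correlation(X).values
        assert np.all(np.abs(R[~np.eye(6, dtype=bool)]) < 0.02)

    def test_too_few_rows_rejected(self):
        with pytest.raises(I.DegenerateInputError):
            I.sample_correlation(np.zeros((2, 3)))

    def test_zero_variance_column_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 1.0
        with pytest.raises(I.DegenerateInputError):
            I.sample_correlation(X)


class TestCronbachAlpha:
    def test_identity_gives_zero(self):
        assert I.cronbach_alpha(np.eye(6)).value == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "k,r,expected",
        [(6, 0.31172707889125795, 0.731), (2, 0.5, 2 / 3), (12, 0.31238, 0.845)],
    )
    def test_equicorrelated_closed_form(self, k, r, expected):
        value = I.cronbach_alpha(equicorrelated(k, r)).value
        assert value == pytest.approx(expected, abs=1e-4)


class TestMinresFactorAnalysis:
    def test_exact_one_factor_recovery(self):
        lam = np.array([0.4, 0.5, 0.6, 0.7, 0.75, 0.8])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        fit = I.efa_minres(R, 1)
        assert fit.converged
        np.testing.assert_allclose(np.abs(fit.loadings[:, 0]), lam, atol=1e-6)

    def test_identity_has_no_common_factor(self):
        fit = I.efa_minres(np.eye(6), 1)
        assert np.all(np.abs(fit.loadings) < 0.1)
        assert np.all(fit.uniquenesses > 0.9)

    def test_equicorrelation_equal_loadings(self):
        fit = I.efa_minres(equicorrelated(6, 0.31173), 1)
        np.testing.assert_allclose(
            np.abs(fit.loadings[:, 0]), np.sqrt(0.31173), atol=1e-6
        )

    def test_unidentified_model_rejected(self):
        with pytest.raises(ValueError, match="unidentified"):
            I.efa_minres(np.eye(6), 4)


class TestOmegaTotal:
    def test_identity_near_zero(self):
        assert I.omega_total(np.eye(6)).value == pytest.approx(0.0, abs=0.02)

    def test_population_tau_equivalence_identity_with_alpha(self):
        R = equicorrelated(6, 0.31172707889125795)
        assert I.omega_total(R, m=1).value == pytest.approx(0.731, abs=1e-6)

    def test_omega_at_least_alpha_on_one_factor_populations(self, rng):
        for _ in range(10):
            lam = rng.uniform(0.3, 0.9, size=6)
            R = np.outer(lam, lam)
            np.fill_diagonal(R, 1.0)
            om = I.omega_total(R, m=1).value
            al = I.cronbach_alpha(R).value
            assert om >= al - 1e-6


class TestGlbFactor:
    def test_identity_gives_zero(self):
        assert I.glb_factor(np.eye(6), m=1).value == pytest.approx(0.0, abs=0.02)

    def test_matches_omega_on_exact_one_factor_matrix(self):
        lam = np.array([0.4, 0.5, 0.6, 0.7, 0.75, 0.8])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        assert I.glb_factor(R, m=1).value == pytest.approx(
            I.omega_total(R, m=1).value, abs=1e-8
        )

    def test_two_item_closed_form(self):
        assert I.glb_factor(equicorrelated(2, 0.5), m=1).value == pytest.approx(
            2 * 0.5 / 1.5, abs=1e-6
        )


def glb_oracle_3x3(R: np.ndarray, step: float = 0.002) -> float:
    """Brute-force algebraic GLB for a 3x3 matrix.

    Grids the first two error variances; for each pair the largest
    feasible third variance follows in closed form from the 3x3 PSD
    characterization (every principal minor non-negative; the
    determinant is linear in y3).
    """
    a, b, c = R[0, 1], R[0, 2], R[1, 2]
    g = np.arange(0.0, 1.0 + step, step)
    y1, y2 = np.meshgrid(g, g, indexing="ij")
    d1, d2 = 1 - y1, 1 - y2
    lead2 = d1 * d2 - a**2
    feasible = lead2 >= -1e-12
    # det(R - diag(y)) = A - y3 * lead2, expanded at y3 = 0
    A = d1 * (d2 - c**2) - a * (a - b * c) + b * (a * c - d2 * b)
    with np.errstate(divide="ignore", invalid="ignore"):
        cap_13 = np.where(d1 > 1e-12, 1 - b**2 / d1, np.where(b**2 <= 1e-12, 1.0, -1.0))
        cap_23 = np.where(d2 > 1e-12, 1 - c**2 / d2, np.where(c**2 <= 1e-12, 1.0, -1.0))
        cap_det = np.where(
            lead2 > 1e-12, A / lead2, np.where(A >= -1e-12, 1.0, -1.0)
        )
    y3 = np.minimum(np.minimum(cap_13, cap_23), np.minimum(cap_det, 1.0))
    total = np.where(feasible & (y3 >= 0), y1 + y2 + y3, -np.inf)
    return 1.0 - total.max() / R.sum()


class TestGlbAlgebraic:
    def test_identity_analytic_optimum(self):
        # all error variances reach 1, so the bound is exactly zero
        assert I.glb_algebraic(np.eye(6)).value == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_two_item_closed_form(self, r):
        assert I.glb_algebraic(equicorrelated(2, r)).value == pytest.approx(
            2 * r / (1 + r), abs=1e-6
        )

    def test_matches_grid_oracle_on_random_3x3(self, rng):
        for _ in range(12):
            R = random_correlation(rng, 3)
            if R.sum() <= 0.5:
                continue
            assert I.glb_algebraic(R).value == pytest.approx(
                glb_oracle_3x3(R), abs=5e-3
            )

    def test_at_least_alpha_on_random_psd(self, rng):
        for _ in range(200):
            k = int(rng.integers(3, 10))
            R = random_correlation(rng, k)
            if R.sum() <= 0:
                continue
            assert I.glb_algebraic(R).value >= I.cronbach_alpha(R).value - 1e-6

    def test_at_least_factor_glb_on_random_psd(self, rng):
        for _ in range(60):
            k = int(rng.integers(4, 10))
            R = random_correlation(rng, k)
            assert (
                I.glb_algebraic(R).value
                >= I.glb_factor(R, m=1).value - 1e-6
            )


class TestEstimatorContracts:
    def test_values_within_unit_interval(self, rng):
        for _ in range(30):
            R = random_correlation(rng, 6)
            for iv in (
                I.omega_total(R),
                I.glb_factor(R),
                I.glb_algebraic(R),
            ):
                assert iv.ok
                assert 0.0 <= iv.value <= 1.0

    def test_population_recovery_all_estimators(self):
        R = P.build_tau_equivalent(6, 0.731).sigma
        assert I.cronbach_alpha(R).value == pytest.approx(0.731, abs=1e-6)
        assert I.omega_total(R, m=1).value == pytest.approx(0.731, abs=1e-6)
        assert I.glb_factor(R, m=1).value == pytest.approx(0.731, abs=1e-6)
        assert I.glb_algebraic(R).value == pytest.approx(0.731, abs=1e-6)

    def test_determinism(self, rng):
        R = random_correlation(rng, 6)
        assert I.cronbach_alpha(R).value == I.cronbach_alpha(R).value
        assert I.glb_algebraic(R).value == I.glb_algebraic(R).value
        a = I.efa_minres(R, 3).uniquenesses
        b = I.efa_minres(R, 3).uniquenesses
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestOmegaReliability:
    def test_no_flip_on_population_matrix(self):
        R = P.build_tau_equivalent(6, 0.731).sigma
        rep = I.omega_reliability(R, m=1)
        assert rep.n_flipped == 0
        assert rep.alpha.value == pytest.approx(0.731, abs=1e-6)
        assert rep.omega_total.value == pytest.approx(0.731, abs=1e-6)

    def test_reverse_keys_a_negated_item(self):
        R = P.build_tau_equivalent(6, 0.731).sigma.copy()
        d = np.ones(6)
        d[2] = -1.0
        R_neg = R * np.outer(d, d)
        rep = I.omega_reliability(R_neg, m=1)
        assert rep.n_flipped == 1
        assert bool(rep.flipped[2])
        # flipping restores the positively keyed population values
        assert rep.alpha.value == pytest.approx(0.731, abs=1e-6)

    def test_keying_free_mode_leaves_matrix_alone(self):
        R = P.build_tau_equivalent(6, 0.731).sigma.copy()
        d = np.ones(6)
        d[2] = -1.0
        R_neg = R * np.outer(d, d)
        rep = I.omega_reliability(R_neg, m=1, reverse_key=False)
        assert rep.n_flipped == 0
        assert rep.alpha.value < 0.731 - 0.1

    def test_inflates_alpha_under_null_samples(self, rng):
        # the data-driven flip can only raise the correlation total
        for _ in range(10):
            X = rng.standard_normal((20, 6))
            R = I.sample_correlation(X)
            flipped = I.omega_reliability(R).alpha.value
            plain = I.cronbach_alpha(R).value
            assert flipped >= plain - 1e-9


class TestComputeAll:
    def test_all_estimators_present(self, rng):
        X = rng.standard_normal((100, 6))
        out = I.compute_all(I.sample_correlation(X))
        assert set(out) == {"alpha", "omega", "glb", "glba"}
        assert all(iv.ok for iv in out.values())

    def test_reverse_key_changes_alpha_omega_only(self, rng):
        X = rng.standard_normal((30, 6))
        R = I.sample_correlation(X)
        plain = I.compute_all(R, reverse_key=False)
        keyed = I.compute_all(R, reverse_key=True)
        assert keyed["glb"].value == plain["glb"].value
        assert keyed["glba"].value == plain["glba"].value
        assert keyed["alpha"].value >= plain["alpha"].value - 1e-9
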