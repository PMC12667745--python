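"""Rayleigh quotient, generalized eigensolver, and its algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhopca import (
    CovariancePair,
    random_spd_pair,
    rayleigh_quotient,
    solve_rho_pca,
)
from rhopca.errors import DegenerateBackgroundError, InvalidInputError, SingularBackgroundError

from conftest import brute_force_geneig


class TestRayleighQuotient:
    @pytest.mark.parametrize(
        "st_, sb_, v, expected",
        [
            (np.eye(2), np.eye(2), [1.0, 0.0], 1.0),
            (np.diag([4.0, 1.0]), np.eye(2), [1.0, 0.0], 4.0),
            # hand-expanded quadratic forms: (2+2*1+2)/(1+2) = 3/1.5
            ([[2.0, 1.0], [1.0, 2.0]], np.diag([1.0, 2.0]),
             np.array([1.0, 1.0]) / np.sqrt(2), 2.0),
        ],
    )
    def test_known_values(self, st_, sb_, v, expected):
        pair = CovariancePair(np.asarray(st_, float), np.asarray(sb_, float))
        assert rayleigh_quotient(v, pair) == pytest.approx(expected)

    def test_scaling_invariance_in_v(self, rng):
        pair = random_spd_pair(4, condition=20.0, seed=7)
        v = rng.standard_normal(4)
        assert rayleigh_quotient(3.7 * v, pair) == pytest.approx(
            rayleigh_quotient(v, pair), rel=1e-12
        )

    def test_zero_vector_rejected(self):
        pair = CovariancePair(np.eye(2), np.eye(2))
        with pytest.raises(InvalidInputError, match="nonzero"):
            rayleigh_quotient([0.0, 0.0], pair)

    def test_null_space_direction_is_error_not_inf(self):
        pair = CovariancePair(np.eye(2), np.diag([1.0, 0.0]))
        with pytest.raises(DegenerateBackgroundError, match="sigma_b"):
            rayleigh_quotient([0.0, 1.0], pair)


class TestSolveRhoPCA:
    def test_identity_background_reduces_to_pca(self):
        sol = solve_rho_pca(CovariancePair(np.diag([3.0, 1.0]), np.eye(2)), d=2)
        assert np.allclose(sol.values, [3.0, 1.0])
        assert np.allclose(np.abs(sol.vectors), np.eye(2), atol=1e-12)

    def test_diagonal_pair_closed_form(self, diag_pair):
        sol = solve_rho_pca(diag_pair, d=2)
        assert np.allclose(sol.values, [4.0, 2.0])
        # first vector along e1, normalized so v' sigma_b v = 1 -> (1/sqrt 2, 0)
        assert np.allclose(sol.vectors[:, 0], [1 / np.sqrt(2), 0.0], atol=1e-12)

    def test_b_orthonormality_and_eigenpair_consistency(self, spd_pairs):
        for pair in spd_pairs:
            sol = solve_rho_pca(pair)
            gram = sol.vectors.T @ pair.sigma_b @ sol.vectors
            assert np.max(np.abs(gram - np.eye(sol.d))) < 1e-6
            for lam, v in zip(sol.values, sol.vectors.T):
                rho = rayleigh_quotient(v, pair)
                assert abs(lam - rho) <= 1e-8 * (1 + abs(lam))

    def test_matches_brute_force_oracle(self, spd_pairs):
        for pair in spd_pairs:
            sol = solve_rho_pca(pair)
            w_ref, v_ref = brute_force_geneig(pair.sigma_t, pair.sigma_b)
            assert np.allclose(sol.values, w_ref, rtol=1e-8)
            for i in range(sol.d):
                gaps = np.abs(w_ref - w_ref[i])
                gaps[i] = np.inf
                if gaps.min() < 1e-6 * max(abs(w_ref[i]), 1.0):
                    continue  # clustered eigenvalue: compare subspaces elsewhere
                cos = abs(sol.vectors[:, i] @ v_ref[:, i]) / (
                    np.linalg.norm(sol.vectors[:, i]) * np.linalg.norm(v_ref[:, i])
                )
                assert cos > 1 - 1e-8

    def test_top_value_is_variational_maximum(self, rng):
        for seed in range(10):
            pair = random_spd_pair(2, condition=30.0, seed=seed)
            sol = solve_rho_pca(pair, d=1)
            thetas = np.linspace(0, np.pi, 1800, endpoint=False)
            grid = np.array(
                [rayleigh_quotient([np.cos(t), np.sin(t)], pair) for t in thetas]
            )
            assert sol.values[0] >= grid.max() - 1e-12 * abs(sol.values[0])
            assert grid.max() == pytest.approx(sol.values[0], rel=1e-4)

    def test_sign_convention(self, spd_pairs):
        for pair in spd_pairs[:5]:
            sol = solve_rho_pca(pair)
            idx = np.argmax(np.abs(sol.vectors), axis=0)
            assert np.all(sol.vectors[idx, np.arange(sol.d)] > 0)

    def test_explicit_mu_on_singular_background_errors(self):
        pair = CovariancePair(np.eye(2), np.diag([1.0, 0.0]))
        with pytest.raises(SingularBackgroundError, match="regulariz|increase mu"):
            solve_rho_pca(pair, mu=0.0)

    def test_auto_mu_on_singular_background_succeeds(self):
        pair = CovariancePair(np.diag([5.0, 1.0]), np.diag([1.0, 0.0]))
        sol = solve_rho_pca(pair, mu="auto")
        assert sol.mu > 0
        gram = sol.vectors.T @ (pair.sigma_b + sol.mu * np.eye(2)) @ sol.vectors
        assert np.allclose(gram, np.eye(2), atol=1e-6)

    def test_d_out_of_range(self, diag_pair):
        with pytest.raises(InvalidInputError):
            solve_rho_pca(diag_pair, d=3)


class TestAlgebraicProperties:
    """Scale invariance, monotonicity, rotational equivariance of the quotient."""

    def test_scale_invariance(self):
        for seed in range(10):
            pair = random_spd_pair(5, condition=20.0, seed=seed)
            a, b = 2.5, 0.4
            sol = solve_rho_pca(pair)
            scaled = solve_rho_pca(
                CovariancePair(a * pair.sigma_t, b * pair.sigma_b)
            )
            assert np.allclose(scaled.values, (a / b) * sol.values, rtol=1e-8)
            # identical eigenvector span: principal angles ~ 0
            q1, _ = np.linalg.qr(sol.vectors)
            q2, _ = np.linalg.qr(scaled.vectors)
            sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
            assert np.min(sv) > 1 - 1e-8

    def test_monotonicity_under_loewner_dominance(self, rng):
        for seed in range(10):
            pair = random_spd_pair(4, condition=10.0, seed=seed)
            bump = rng.standard_normal((4, 4))
            bigger_t = pair.sigma_t + bump @ bump.T  # dominates sigma_t
            pair_big = CovariancePair(bigger_t, pair.sigma_b)
            for _ in range(10):
                v = rng.standard_normal(4)
                assert rayleigh_quotient(v, pair_big) >= rayleigh_quotient(v, pair) - 1e-10
            # symmetric claim: enlarging the background can only decrease rho
            bigger_b = pair.sigma_b + bump @ bump.T
            pair_bigb = CovariancePair(pair.sigma_t, bigger_b)
            for _ in range(10):
                v = rng.standard_normal(4)
                assert rayleigh_quotient(v, pair_bigb) <= rayleigh_quotient(v, pair) + 1e-10

    def test_rotational_equivariance(self, rng):
        for seed in range(10):
            pair = random_spd_pair(4, condition=10.0, seed=100 + seed)
            q, r = np.linalg.qr(rng.standard_normal((4, 4)))
            q *= np.sign(np.diag(r))
            rotated = CovariancePair(q @ pair.sigma_t @ q.T, q @ pair.sigma_b @ q.T)
            sol = solve_rho_pca(pair)
            sol_rot = solve_rho_pca(rotated)
            assert np.allclose(sol_rot.values, sol.values, atol=1e-8 * (1 + np.max(np.abs(sol.values))))
            for i in range(4):
                expected = q @ sol.vectors[:, i]
                cos = abs(expected @ sol_rot.vectors[:, i]) / (
                    np.linalg.norm(expected) * np.linalg.norm(sol_rot.vectors[:, i])
                )
                assert cos > 1 - 1e-8


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000), dim=st.integers(2, 8))
def test_property_solver_matches_oracle(seed, dim):
    """Eigenvalues of the solver always match the dense inv(B)@A oracle."""
    pair = random_spd_pair(dim, condition=100.0, seed=seed)
    sol = solve_rho_pca(pair)
    w_ref, _ = brute_force_geneig(pair.sigma_t, pair.sigma_b)
    assert np.allclose(sol.values, w_ref, rtol=1e-7, atol=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_property_lambda1_upper_bounds_random_directions(seed):
    """lambda_1 dominates the quotient at arbitrary directions (variational bound)."""
    rng = np.random.default_rng(seed)
    pair = random_spd_pair(5, condition=50.0, seed=seed)
    lam1 = solve_rho_pca(pair, d=1).values[0]
    for _ in range(20):
        v = rng.standard_normal(5)
        assert rayleigh_quotient(v, pair) <= lam1 * (1 + 1e-10)
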