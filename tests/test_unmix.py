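"""SISAL simplex fitting, Dirichlet-mixture GEM and the unmixing pipeline."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rodeca.core import HyperspectralCube
from rodeca.evaluate import match_endmembers
from rodeca.subspace import SubspaceModel, hysime, project
from rodeca.synth import simulate_case
from rodeca.unmix import (
    EmConfig,
    SisalConfig,
    UnmixConfig,
    compute_abundance,
    recover_endmembers,
    rodeca_em,
    simplex_project,
    sisal,
    unmix,
    vca,
)


def random_simplex_data(p, N, seed, pure=False):
    rng = np.random.default_rng(seed)
    A = rng.random((p, p)) + np.eye(p)  # well-conditioned vertices
    s = rng.dirichlet(np.ones(p), size=N).T
    if pure:
        s[:, :p] = np.eye(p)
    return A @ s, A, s


class TestSimplexProject:
    def test_interior_points_unchanged(self):
        S = np.array([[0.2, 0.5], [0.3, 0.25], [0.5, 0.25]])
        assert np.allclose(simplex_project(S), S)

    def test_output_on_simplex(self, rng):
        S = rng.normal(size=(4, 100))
        P = simplex_project(S)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=0), 1.0, atol=1e-12)

    def test_matches_qp_oracle(self, rng):
        S = rng.normal(size=(4, 20))
        P = simplex_project(S)
        for i in range(20):
            res = minimize(
                lambda x: 0.5 * np.sum((x - S[:, i]) ** 2),
                np.full(4, 0.25),
                jac=lambda x: x - S[:, i],
                constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
                bounds=[(0.0, None)] * 4,
                method="SLSQP",
                options={"ftol": 1e-14, "maxiter": 200},
            )
            assert np.allclose(P[:, i], res.x, atol=1e-6)


class TestVca:
    def test_pure_pixels_recovered_exactly(self):
        Y, A, _ = random_simplex_data(4, 300, seed=0, pure=True)
        V = vca(Y, 4, seed=1)
        perm = match_endmembers(V, A)
        assert np.allclose(V[:, list(perm)], A, atol=1e-12)

    def test_p_one_returns_max_norm_pixel(self):
        Y = np.array([[1.0, 3.0, 2.0], [0.0, 4.0, 1.0]])
        assert np.array_equal(vca(Y, 1), Y[:, [1]])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            vca(np.ones((3, 10)), 5)


class TestSisal:
    def test_known_simplex_recovered(self):
        rng = np.random.default_rng(2)
        A = rng.random((3, 3)) + np.eye(3)
        s = rng.dirichlet(np.ones(3), size=60).T
        s[:, :3] = np.eye(3)  # the vertices themselves are present
        Y = A @ np.repeat(s, 3, axis=1)
        A_hat = sisal(
            Y,
            3,
            SisalConfig(tau=1.0, seed=0, adapt_tau=False, max_iter=1000, mu_max=1e3),
        )
        perm = match_endmembers(A_hat, A)
        assert np.allclose(A_hat[:, list(perm)], A, atol=1e-6)

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            sisal(np.ones((1, 50)), 1)

    def test_rank_deficient_data_rejected(self):
        Y = np.outer(np.ones(3), np.linspace(1, 2, 40))  # affine rank 1
        with pytest.raises(ValueError, match="affinely span"):
            sisal(Y, 3)

    def test_interior_only_data_encloses_and_locates_vertices(self, case_a_clean):
        # no pure pixels: dominant fractions stop at 0.85
        cube, M_true, _ = case_a_clean
        model = hysime(cube)
        Y = project(cube, model)
        A_hat = sisal(Y, 4, SisalConfig(seed=0))
        S = np.linalg.inv(A_hat) @ Y
        frac_inside = np.mean(S.min(axis=0) >= -1e-6)
        assert frac_inside >= 0.99
        A_true = model.basis.T @ M_true.spectra
        perm = match_endmembers(A_hat, A_true)
        rel = np.linalg.norm(A_hat[:, list(perm)] - A_true, axis=0) / np.linalg.norm(
            A_true, axis=0
        )
        assert rel.max() < 0.05


class TestComputeAbundance:
    def test_exact_mixture_recovered(self):
        Y, A, s = random_simplex_data(4, 200, seed=3)
        ab, n_proj = compute_abundance(np.linalg.inv(A), Y)
        assert np.allclose(ab.fractions, s, atol=1e-9)

    def test_contract_on_arbitrary_input(self, rng):
        W = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        Y = rng.normal(size=(3, 50))
        ab, _ = compute_abundance(W, Y)
        assert np.all(ab.fractions >= 0)
        assert np.allclose(ab.fractions.sum(axis=0), 1.0, atol=1e-12)

    def test_matches_constrained_least_squares_oracle(self, rng):
        # for invertible A the simplex-constrained Euclidean repair of W y is
        # the projection QP; feasible pixels coincide with the exact LS fit
        Y, A, s = random_simplex_data(4, 10, seed=4)
        Yn = Y + rng.normal(0, 0.05, Y.shape)
        W = np.linalg.inv(A)
        ab, _ = compute_abundance(W, Yn)
        S_raw = W @ Yn
        for i in range(10):
            res = minimize(
                lambda x: 0.5 * np.sum((x - S_raw[:, i]) ** 2),
                np.full(4, 0.25),
                jac=lambda x: x - S_raw[:, i],
                constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
                bounds=[(0.0, None)] * 4,
                method="SLSQP",
                options={"ftol": 1e-15, "maxiter": 300},
            )
            assert np.allclose(ab.fractions[:, i], res.x, atol=1e-6)


class TestRecoverEndmembers:
    @staticmethod
    def _identity_model(L, p):
        E = np.eye(L)[:, :p]
        return SubspaceModel(
            p=p, basis=E, noise_variance=np.zeros(L), mse_curve=np.zeros(L + 1)
        )

    def test_normalization_arithmetic(self):
        model = self._identity_model(3, 2)
        A = np.array([[2.0, 1.0], [4.0, 0.5]])
        M = recover_endmembers(np.linalg.inv(A), model).spectra
        # first column (2, 4, 0) -> (0.5, 1, 0)
        assert np.allclose(M[:, 0], [0.5, 1.0, 0.0])

    def test_negative_entries_clipped(self):
        model = self._identity_model(3, 2)
        A = np.array([[-0.2, 1.0], [1.0, 0.2]])
        M = recover_endmembers(np.linalg.inv(A), model).spectra
        assert np.all(M >= 0)
        assert np.allclose(M.max(axis=0), 1.0)


class TestRodecaEm:
    def test_true_simplex_is_a_fixed_point_on_noiseless_data(self, case_a_clean):
        cube, M_true, _ = case_a_clean
        model = hysime(cube)
        Y = project(cube, model)
        A_true = model.basis.T @ M_true.spectra
        W, mixture, trace = rodeca_em(Y, A_true, EmConfig(seed=0))
        assert len(trace) - 1 <= 5  # iterations to converge
        A_out = np.linalg.inv(W)
        assert np.abs(A_out - A_true).max() < 1e-6

    def test_objective_trace_is_monotone(self):
        for seed, snr in [(0, 20.0), (1, 10.0), (2, 40.0)]:
            cube, _, _ = simulate_case("A", snr, seed=seed)
            res = unmix(cube, UnmixConfig(seed=seed))
            tr = res.loglik_trace
            drops = np.diff(tr)
            assert np.all(drops >= -1e-8 * (1.0 + np.abs(tr[:-1])))

    def test_singular_init_rejected(self):
        with pytest.raises(ValueError):
            rodeca_em(np.random.default_rng(0).random((3, 50)), np.ones((3, 3)))


class TestUnmixPipeline:
    def test_noiseless_near_exact_recovery(self, case_a_clean):
        from rodeca.evaluate import evaluate_run

        cube, M_true, s_true = case_a_clean
        res = unmix(cube, UnmixConfig(seed=0))
        assert res.subspace.p == 4
        rep = evaluate_run(
            res.endmembers.spectra,
            res.abundances.fractions,
            M_true.spectra,
            s_true.fractions,
        )
        assert rep.xi_s < 1e-2
        assert rep.xi_M < 1e-2

    def test_noiseless_round_trip_matches_fixture_spectra(self, case_a_clean):
        cube, M_true, _ = case_a_clean
        res = unmix(cube, UnmixConfig(seed=0))
        perm = match_endmembers(res.endmembers.spectra, M_true.spectra)
        diff = np.abs(res.endmembers.spectra[:, list(perm)] - M_true.spectra)
        assert diff.mean() < 1e-3

    def test_each_truth_matched_to_distinct_endmember(self, case_a_20db):
        cube, M_true, _ = case_a_20db
        res = unmix(cube, UnmixConfig(seed=0))
        perm = match_endmembers(res.endmembers.spectra, M_true.spectra)
        assert sorted(perm) == [0, 1, 2, 3]

    def test_same_seed_bit_identical(self, case_a_20db):
        cube, _, _ = case_a_20db
        r1 = unmix(cube, UnmixConfig(seed=11))
        r2 = unmix(cube, UnmixConfig(seed=11))
        assert np.array_equal(r1.endmembers.spectra, r2.endmembers.spectra)
        assert np.array_equal(r1.abundances.fractions, r2.abundances.fractions)
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_scale_equivariance(self, case_a_20db):
        cube, _, _ = case_a_20db
        scaled = HyperspectralCube(
            cube.values * 1234.5, cube.pixel_map, cube.channel_set, cube.canvas_shape
        )
        r1 = unmix(cube, UnmixConfig(seed=2))
        r2 = unmix(scaled, UnmixConfig(seed=2))
        assert np.abs(r1.endmembers.spectra - r2.endmembers.spectra).max() < 1e-6
        assert np.abs(r1.abundances.fractions - r2.abundances.fractions).max() < 1e-6

    def test_seed_freedom_is_only_permutation(self):
        cube, _, _ = simulate_case("A", 40.0, seed=6)
        r1 = unmix(cube, UnmixConfig(seed=1))
        r2 = unmix(cube, UnmixConfig(seed=2))
        perm = match_endmembers(r2.endmembers.spectra, r1.endmembers.spectra)
        diff = np.abs(r2.endmembers.spectra[:, list(perm)] - r1.endmembers.spectra)
        assert diff.max() < 0.05

    def test_errors_shrink_with_less_noise(self):
        from rodeca.evaluate import evaluate_run

        out = {}
        for snr in (10.0, 60.0):
            cube, M_true, s_true = simulate_case("A", snr, seed=3)
            res = unmix(cube, UnmixConfig(seed=3))
            rep = evaluate_run(
                res.endmembers.spectra,
                res.abundances.fractions,
                M_true.spectra,
                s_true.fractions,
            )
            out[snr] = rep
        assert out[60.0].xi_s < out[10.0].xi_s
        assert out[60.0].xi_M < out[10.0].xi_M

    def test_force_p_override(self, case_a_20db):
        cube, _, _ = case_a_20db
        res = unmix(cube, UnmixConfig(seed=0, force_p=3))
        assert res.subspace.p == 3
        assert res.endmembers.spectra.shape == (18, 3)
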