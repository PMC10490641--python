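"""Laplacian, graph Fourier transform, spectral vs Chebyshev filtering."""

import numpy as np
import pytest
from numpy.polynomial import chebyshev as npcheb

from chebseg import (ChebCoefficients, chebyshev_filter, degree_matrix, gft,
                     igft, laplacian, scale_laplacian, spectral_decomposition,
                     spectral_filter)
from conftest import random_weighted_graph


class TestLaplacian:
    @pytest.mark.parametrize("w,expected_diag", [
        ([[0, 1], [1, 0]], [1, 1]),
        ([[0, 2, 0], [2, 0, 1], [0, 1, 0]], [2, 3, 1]),
        (np.zeros((3, 3)), [0, 0, 0]),
    ])
    def test_degree_matrix(self, w, expected_diag):
        d = degree_matrix(np.asarray(w, float))
        assert np.allclose(np.diag(d), expected_diag)
        assert np.allclose(d - np.diag(np.diag(d)), 0)

    def test_path2_laplacian_and_spectrum(self):
        bundle = laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(bundle.laplacian, [[1, -1], [-1, 1]])
        vals = np.linalg.eigvalsh(bundle.laplacian)
        assert np.allclose(vals, [0.0, 2.0])

    def test_zero_row_sums_and_psd_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for n in (4, 7, 10):
            w = random_weighted_graph(rng, n)
            bundle = laplacian(w)
            assert np.max(np.abs(bundle.laplacian.sum(axis=1))) < 1e-9
            assert np.linalg.eigvalsh(bundle.laplacian)[0] > -1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            laplacian(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestDecomposition:
    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            bundle = spectral_decomposition(laplacian(random_weighted_graph(rng, 10)))
            u, lam = bundle.fourier_basis, bundle.eigenvalues
            assert np.max(np.abs(u @ np.diag(lam) @ u.T - bundle.laplacian)) <= 1e-8
            assert np.max(np.abs(u.T @ u - np.eye(10))) <= 1e-10
            assert np.all(np.diff(lam) >= -1e-12)

    def test_gft_roundtrip_and_parseval(self):
        rng = np.random.default_rng(2)
        bundle = spectral_decomposition(laplacian(random_weighted_graph(rng, 8)))
        x = rng.normal(size=8)
        x_hat = gft(x, bundle.fourier_basis)
        assert np.max(np.abs(igft(x_hat, bundle.fourier_basis) - x)) <= 1e-10
        assert np.linalg.norm(x_hat) == pytest.approx(np.linalg.norm(x), abs=1e-10)

    def test_identity_basis_is_identity_transform(self):
        x = np.arange(4.0)
        assert np.array_equal(gft(x, np.eye(4)), x)
        assert np.array_equal(igft(x, np.eye(4)), x)


class TestSpectralFilter:
    def test_identity_and_zero_filters(self):
        rng = np.random.default_rng(3)
        bundle = spectral_decomposition(laplacian(random_weighted_graph(rng, 6)))
        x = rng.normal(size=6)
        assert np.allclose(spectral_filter(x, bundle, np.ones(6)), x)
        assert np.allclose(spectral_filter(x, bundle, np.zeros(6)), 0)

    def test_lambda_filter_applies_scaled_laplacian(self):
        rng = np.random.default_rng(4)
        bundle = scale_laplacian(spectral_decomposition(
            laplacian(random_weighted_graph(rng, 7))))
        lt = bundle.scaled_laplacian
        # decompose L_tilde itself and filter with g(lambda) = lambda
        from chebseg.spectral import SpectralBundle
        vals, vecs = np.linalg.eigh(lt)
        lt_bundle = SpectralBundle(laplacian=lt, degree=np.zeros((7, 7)),
                                   fourier_basis=vecs, eigenvalues=vals)
        x = rng.normal(size=7)
        assert np.max(np.abs(spectral_filter(x, lt_bundle, vals) - lt @ x)) <= 1e-9


class TestScaledLaplacian:
    def test_path2_closed_form(self):
        bundle = scale_laplacian(laplacian(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert np.allclose(bundle.scaled_laplacian, [[0, -1], [-1, 0]])

    def test_spectrum_maps_into_unit_interval(self):
        rng = np.random.default_rng(5)
        for n in (5, 9, 12):
            bundle = scale_laplacian(laplacian(random_weighted_graph(rng, n)))
            vals = np.linalg.eigvalsh(bundle.scaled_laplacian)
            assert vals[0] >= -1 - 1e-9 and vals[-1] <= 1 + 1e-9
            assert vals[0] == pytest.approx(-1.0, abs=1e-9)  # lambda=0 -> -1
            assert vals[-1] == pytest.approx(1.0, abs=1e-9)  # lambda_max -> +1

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            scale_laplacian(laplacian(np.zeros((3, 3))))


class TestChebyshevFilter:
    def test_low_order_special_cases(self):
        rng = np.random.default_rng(6)
        bundle = scale_laplacian(laplacian(random_weighted_graph(rng, 6)))
        lt = bundle.scaled_laplacian
        x = rng.normal(size=(6, 2))
        ident = np.eye(2)
        k1 = ChebCoefficients(theta=ident[None])
        assert np.allclose(chebyshev_filter(x, lt, k1), x)
        k2 = ChebCoefficients(theta=np.stack([np.zeros((2, 2)), ident]))
        assert np.allclose(chebyshev_filter(x, lt, k2), lt @ x)

    def test_matches_exact_spectral_filter(self):
        """Polynomial filtering via the recurrence equals the exact
        eigendecomposition route for random graphs and coefficients."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(1, 6))
            w = random_weighted_graph(rng, n)
            bundle = scale_laplacian(laplacian(w))
            lt = bundle.scaled_laplacian
            vals, vecs = np.linalg.eigh(lt)
            theta = rng.normal(size=k)
            x = rng.normal(size=n)
            via_cheb = chebyshev_filter(x, lt, ChebCoefficients(theta=theta))
            g = npcheb.chebval(vals, theta)
            from chebseg.spectral import SpectralBundle
            lt_bundle = SpectralBundle(laplacian=lt, degree=np.zeros((n, n)),
                                       fourier_basis=vecs, eigenvalues=vals)
            via_spectral = spectral_filter(x, lt_bundle, g)
            assert np.max(np.abs(via_cheb - via_spectral)) <= 1e-8

    def test_linearity(self):
        rng = np.random.default_rng(8)
        bundle = scale_laplacian(laplacian(random_weighted_graph(rng, 9)))
        lt = bundle.scaled_laplacian
        coeff = ChebCoefficients(theta=rng.normal(size=4))
        x, z = rng.normal(size=9), rng.normal(size=9)
        a, b = 2.5, -1.3
        lhs = chebyshev_filter(a * x + b * z, lt, coeff)
        rhs = a * chebyshev_filter(x, lt, coeff) + b * chebyshev_filter(z, lt, coeff)
        assert np.max(np.abs(lhs - rhs)) <= 1e-9

    def test_locality_on_path_graph(self):
        """A K-order filter reaches only K-1 hops: perturbing a far node
        leaves the output at node 0 unchanged."""
        n, k = 10, 3
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        lt = scale_laplacian(laplacian(w)).scaled_laplacian
        coeff = ChebCoefficients(theta=np.array([0.7, -0.2, 0.4]))
        x = np.zeros(n)
        base = chebyshev_filter(x, lt, coeff)
        x_far = x.copy()
        x_far[k] = 5.0  # distance 3 > K-1 = 2 hops from node 0
        pert = chebyshev_filter(x_far, lt, coeff)
        assert pert[0] == pytest.approx(base[0], abs=1e-12)
        x_near = x.copy()
        x_near[k - 1] = 5.0
        assert abs(chebyshev_filter(x_near, lt, coeff)[0] - base[0]) > 1e-8

    def test_constant_signal_is_eigenvector(self):
        rng = np.random.default_rng(9)
        w = random_weighted_graph(rng, 7)
        lt = scale_laplacian(laplacian(w)).scaled_laplacian
        theta = rng.normal(size=4)
        ones = np.ones(7)
        out = chebyshev_filter(ones, lt, ChebCoefficients(theta=theta))
        expected = npcheb.chebval(-1.0, theta)  # eigenvalue 0 maps to -1
        assert np.allclose(out, expected * ones, atol=1e-9)

    def test_channel_mismatch_rejected(self):
        lt = np.zeros((3, 3))
        with pytest.raises(ValueError):
            chebyshev_filter(np.zeros((3, 2)), lt,
                             ChebCoefficients(theta=np.zeros((2, 4, 4))))
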