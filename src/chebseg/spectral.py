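"""Graph-signal-processing kernel: combinatorial Laplacian, graph Fourier
transform, exact spectral filtering, and K-order Chebyshev filtering.

The Laplacian is the unnormalized L = D - W.  Because its largest
eigenvalue is unbounded, the rescaled operator

    L_tilde = 2 L / lambda_max - I

(with lambda_max computed by an exact symmetric eigensolve; graphs here
have at most ~1000 nodes) maps the spectrum into [-1, 1], where Chebyshev
polynomials T_k are well-behaved.  Filtering with coefficients theta_k,

    y = sum_k theta_k T_k(L_tilde) x,

is evaluated through the three-term recurrence on vectors
T_0 x = x, T_1 x = L_tilde x, T_k x = 2 L_tilde T_{k-1} x - T_{k-2} x,
never forming dense polynomial matrices.  The exact spectral route
y = U g(Lambda) U^T x serves as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SpectralBundle",
    "ChebCoefficients",
    "degree_matrix",
    "laplacian",
    "spectral_decomposition",
    "gft",
    "igft",
    "spectral_filter",
    "scale_laplacian",
    "chebyshev_filter",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class SpectralBundle:
    """Laplacian quantities for one graph; optional fields filled lazily."""

    laplacian: np.ndarray
    degree: np.ndarray
    fourier_basis: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    lambda_max: float | None = None
    scaled_laplacian: np.ndarray | None = None


@dataclass(frozen=True)
class ChebCoefficients:
    """theta[k, f_in, f_out] for a K-order polynomial filter bank."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=np.float64)
        if th.ndim == 1:
            th = th[:, None, None]
        if th.ndim != 3 or th.shape[0] < 1:
            raise ValueError("theta must have shape (K, f_in, f_out) with K >= 1")
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", th)

    @property
    def order(self) -> int:
        return self.theta.shape[0]


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.max(np.abs(w - w.T)) > _SYM_TOL:
        raise ValueError("weight matrix must be symmetric")
    return w


def degree_matrix(weights: np.ndarray) -> np.ndarray:
    """Diagonal degree matrix D_ii = sum_j W_ij."""
    w = _check_weights(weights)
    return np.diag(w.sum(axis=1))


def laplacian(weights: np.ndarray) -> SpectralBundle:
    """Combinatorial Laplacian L = D - W (symmetric, zero row sums)."""
    w = _check_weights(weights)
    d = degree_matrix(w)
    return SpectralBundle(laplacian=d - w, degree=d)


def spectral_decomposition(bundle: SpectralBundle) -> SpectralBundle:
    """Eigendecompose L = U Lambda U^T with ascending eigenvalues."""
    vals, vecs = np.linalg.eigh(bundle.laplacian)
    return replace(bundle, fourier_basis=vecs, eigenvalues=vals,
                   lambda_max=float(vals[-1]))


def gft(signal: np.ndarray, fourier_basis: np.ndarray) -> np.ndarray:
    """Graph Fourier transform x_hat = U^T x."""
    signal = np.asarray(signal)
    if signal.shape[0] != fourier_basis.shape[0]:
        raise ValueError("signal length must match the Fourier basis")
    return fourier_basis.T @ signal


def igft(transformed: np.ndarray, fourier_basis: np.ndarray) -> np.ndarray:
    """Inverse GFT x = U x_hat."""
    transformed = np.asarray(transformed)
    if transformed.shape[0] != fourier_basis.shape[0]:
        raise ValueError("coefficient length must match the Fourier basis")
    return fourier_basis @ transformed


def spectral_filter(signal: np.ndarray, bundle: SpectralBundle,
                    filter_values: np.ndarray) -> np.ndarray:
    """Exact spectral filtering y = U diag(g) U^T x (test oracle route)."""
    if bundle.fourier_basis is None:
        bundle = spectral_decomposition(bundle)
    u = bundle.fourier_basis
    g = np.asarray(filter_values)
    if g.shape[0] != u.shape[0]:
        raise ValueError("filter_values length must match the graph size")
    x_hat = gft(signal, u)
    if x_hat.ndim > 1:
        g = g[:, None]
    return igft(g * x_hat, u)


def scale_laplacian(bundle: SpectralBundle) -> SpectralBundle:
    """Rescale: L_tilde = 2 L / lambda_max - I, spectrum in [-1, 1]."""
    if bundle.lambda_max is None:
        lam_max = float(np.linalg.eigvalsh(bundle.laplacian)[-1])
        bundle = replace(bundle, lambda_max=lam_max)
    if bundle.lambda_max <= 0:
        raise ValueError("lambda_max must be positive (graph has no edges?)")
    n = bundle.laplacian.shape[0]
    lt = 2.0 * bundle.laplacian / bundle.lambda_max - np.eye(n)
    return replace(bundle, scaled_laplacian=lt)


def chebyshev_filter(signals: np.ndarray, scaled_laplacian: np.ndarray,
                     coefficients: ChebCoefficients) -> np.ndarray:
    """K-order Chebyshev filtering of node signals (N x F_in -> N x F_out).

    Runs the three-term recurrence on the signal matrix and contracts each
    T_k x with theta[k] over input channels.
    """
    x = np.asarray(signals, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    theta = coefficients.theta
    if x.shape[1] != theta.shape[1]:
        raise ValueError(
            f"signal has {x.shape[1]} channels but theta expects {theta.shape[1]}")
    k_order = coefficients.order
    t_prev = x
    out = t_prev @ theta[0]
    if k_order > 1:
        t_curr = scaled_laplacian @ x
        out = out + t_curr @ theta[1]
        for k in range(2, k_order):
            t_next = 2.0 * (scaled_laplacian @ t_curr) - t_prev
            out = out + t_next @ theta[k]
            t_prev, t_curr = t_curr, t_next
    if squeeze and out.shape[1] == 1:
        out = out[:, 0]
    return out
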