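"""Closed-form frequency response of the spectral graph model.

Regional activity under white-noise drive is assembled, per frequency, as a
sum over the complex-Laplacian eigenmodes:

    X(omega) = [ sum_k  u_k u_k^H / (i*omega + lambda_k(omega) F_G(omega)/tau_G) ]
               * F_G(omega) * H_local(omega) * P(omega)

where F_G is the Gamma-shaped long-range impulse response (time constant
tau_G), H_local the mesoscopic E-I transfer, and P the input noise spectrum
(flat by default).  The eigenmode sum (``eigen_sum``) is the model as
printed; ``direct_solve`` evaluates the exact resolvent
(i*omega*I + F_G L(omega)/tau_G)^{-1} instead.  For zero-delay (real
symmetric) Laplacians the two coincide; at nonzero delay the outer-product
sum is an approximation of the resolvent (right eigenvectors only) and the
difference is measurable, not hidden.

Because L(omega) = I - alpha*B(omega) with B independent of every fitted
parameter, the eigendecomposition of B over a frequency grid is cached once
per connectome (:class:`SpectralCache`) and re-used across parameter values:
lambda_k(omega) = 1 - alpha*mu_k(omega) with unchanged eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .connectome_io import ConnectomeGraph, RegionalPSD, SpatialProfile
from .graph_spectrum import (
    LaplacianSpec,
    _phase_fix,
    build_complex_laplacian,
    normalized_complex_adjacency,
)
from .local_model import SGMParameters, UnstableParametersError, gamma_response, local_transfer

DB_FLOOR = 1e-30
_RESOLVENT_ATOL = 1e-12


def default_grid(f_lo: float = 2.0, f_hi: float = 45.0, step: float = 0.5) -> np.ndarray:
    """Default evaluation grid: 2-45 Hz in 0.5 Hz steps (87 bins)."""
    n = int(round((f_hi - f_lo) / step))
    return f_lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class NoiseModel:
    """Input noise spectrum P(omega).

    ``independent_per_region``: i.i.d. unit-variance white noise at every
    region, so S_j = sum_m |T_jm|^2 |P|^2 (row power of the transfer).
    ``common``: one shared noise realization, S_j = |sum_m T_jm|^2 |P|^2.
    """

    mode: str = "independent_per_region"  # | "common"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("independent_per_region", "common"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.amplitude <= 0:
            raise ValueError("noise amplitude must be > 0")


@dataclass
class ModelResponse:
    frequency_hz: float
    transfer: np.ndarray  # (N, N) complex


class SpectralCache:
    """Per-frequency eigendecomposition of the normalized complex adjacency.

    ``mu[f, k]`` and ``U[f, :, k]`` are eigenpairs of B(omega); they depend
    only on the connectome, the normalization, the conduction speed and the
    grid — not on any fitted parameter.
    """

    def __init__(
        self,
        graph: ConnectomeGraph,
        grid: np.ndarray,
        speed_v: float = 5.0,
        normalization: str = "symmetric_degree",
    ):
        self.graph = graph
        self.grid = np.asarray(grid, dtype=float)
        self.speed_v = speed_v
        self.normalization = normalization
        n = graph.n_regions
        nf = self.grid.size
        self.mu = np.empty((nf, n), dtype=complex)
        self.U = np.empty((nf, n, n), dtype=complex)
        spec = LaplacianSpec(alpha=1.0, speed_v=speed_v, normalization=normalization)
        for i, f in enumerate(self.grid):
            B = normalized_complex_adjacency(graph, float(f), spec)
            mu, U = scipy.linalg.eig(B)
            U = _phase_fix(U / np.linalg.norm(U, axis=0))
            self.mu[i] = mu
            self.U[i] = U

    def laplacian_eigenvalues(self, alpha: float) -> np.ndarray:
        """lambda_k(omega) = 1 - alpha * mu_k(omega), shape (F, N)."""
        return 1.0 - alpha * self.mu


def _scalar_factors(grid: np.ndarray, params: SGMParameters):
    """F_G(omega) * H_local(omega) and the per-frequency i*omega term."""
    FG = gamma_response(grid, params.tau_G)
    H = local_transfer(grid, params)
    return FG, H


def eqn1_transfer(
    graph: ConnectomeGraph,
    params: SGMParameters,
    f: float,
    method: str = "eigen_sum",
    normalization: str = "symmetric_degree",
) -> ModelResponse:
    """N x N transfer T(omega) from regional noise inputs to regional outputs.

    ``eigen_sum`` (default) is the eigenmode summation; ``direct_solve`` is
    the dense-resolvent oracle.  Both apply the same scalar F_G * H_local
    factor.  A near-singular resolvent raises
    :class:`~brainsgm.local_model.UnstableParametersError`.
    """
    if method not in ("eigen_sum", "direct_solve"):
        raise ValueError(f"unknown method {method!r}")
    omega = 2.0 * np.pi * f
    FG = complex(gamma_response(f, params.tau_G))
    H = complex(local_transfer(f, params))
    spec = LaplacianSpec(
        alpha=params.alpha, speed_v=params.speed_v, normalization=normalization
    )
    L = build_complex_laplacian(graph, f, spec)
    if method == "direct_solve":
        M = 1j * omega * np.eye(graph.n_regions) + (FG / params.tau_G) * L
        T = np.linalg.solve(M, np.eye(graph.n_regions, dtype=complex)) * (FG * H)
        return ModelResponse(f, T)
    lam, U = scipy.linalg.eig(L)
    U = _phase_fix(U / np.linalg.norm(U, axis=0))
    den = 1j * omega + lam * FG / params.tau_G
    if np.min(np.abs(den)) < _RESOLVENT_ATOL:
        raise UnstableParametersError("singular resolvent in eigenmode sum")
    T = (U * (1.0 / den)) @ U.conj().T * (FG * H)
    return ModelResponse(f, T)


def _psd_from_cache(
    cache: SpectralCache, params: SGMParameters, noise: NoiseModel
) -> np.ndarray:
    """Row-power spectra over the whole grid using cached eigenmodes."""
    grid = cache.grid
    omega = 2.0 * np.pi * grid
    FG, H = _scalar_factors(grid, params)
    n = cache.graph.n_regions
    if params.alpha == 0:
        # L = I exactly: the network decouples and every region sees the same
        # scalar filter F_G * H_local / (i*omega + F_G / tau_G)
        den0 = 1j * omega + FG / params.tau_G
        if np.min(np.abs(den0)) < _RESOLVENT_ATOL:
            raise UnstableParametersError("singular resolvent in eigenmode sum")
        S_scalar = np.abs(FG * H / den0) ** 2 * noise.amplitude**2
        return np.tile(S_scalar, (n, 1))
    lam = cache.laplacian_eigenvalues(params.alpha)  # (F, N)
    den = 1j * omega[:, None] + lam * (FG / params.tau_G)[:, None]
    if np.min(np.abs(den)) < _RESOLVENT_ATOL:
        raise UnstableParametersError("singular resolvent in eigenmode sum")
    scalar = FG * H  # (F,)
    U = cache.U
    # T_f = U_f diag(1/den_f) U_f^H * scalar_f
    T = np.einsum("fik,fk,fjk->fij", U, 1.0 / den, U.conj(), optimize=True)
    T *= scalar[:, None, None]
    if noise.mode == "independent_per_region":
        S = np.sum(np.abs(T) ** 2, axis=2)  # (F, N)
    else:
        S = np.abs(T.sum(axis=2)) ** 2
    return (S * noise.amplitude**2).T  # (N, F)


def forward_psd(
    graph: ConnectomeGraph,
    params: SGMParameters,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    method: str = "eigen_sum",
    normalization: str = "symmetric_degree",
    cache: SpectralCache | None = None,
) -> RegionalPSD:
    """Regional raw-power spectral density over a frequency grid.

    A precomputed :class:`SpectralCache` may be passed to amortize the
    eigendecompositions across repeated calls with different parameters
    (the inference loop does this); results are identical either way.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    noise = noise or NoiseModel()
    if method == "eigen_sum":
        if cache is None:
            cache = SpectralCache(graph, grid, params.speed_v, normalization)
        values = _psd_from_cache(cache, params, noise)
    else:
        n = graph.n_regions
        values = np.empty((n, grid.size))
        for i, f in enumerate(grid):
            T = eqn1_transfer(graph, params, float(f), method, normalization).transfer
            if noise.mode == "independent_per_region":
                values[:, i] = np.sum(np.abs(T) ** 2, axis=1) * noise.amplitude**2
            else:
                values[:, i] = np.abs(T.sum(axis=1)) ** 2 * noise.amplitude**2
    return RegionalPSD(graph.region_labels, grid, values, scale="raw_power")


def to_db(psd: RegionalPSD) -> RegionalPSD:
    """10*log10(max(S, 1e-30)): dB scale with a floor so zeros stay finite."""
    if psd.scale != "raw_power":
        raise ValueError("to_db expects raw power input")
    values = 10.0 * np.log10(np.maximum(psd.values, DB_FLOOR))
    return RegionalPSD(psd.region_labels, psd.frequencies_hz, values, scale="dB")


def from_db(psd: RegionalPSD) -> RegionalPSD:
    """Inverse of :func:`to_db` above the floor."""
    if psd.scale != "dB":
        raise ValueError("from_db expects dB input")
    return RegionalPSD(
        psd.region_labels, psd.frequencies_hz, 10.0 ** (psd.values / 10.0), "raw_power"
    )


def band_power(psd: RegionalPSD, band: tuple[float, float] = (8.0, 12.0)) -> SpatialProfile:
    """Per-region trapezoidal integral of raw power over [f_lo, f_hi] (power*Hz).

    The band must lie within the grid range; dB input is rejected because the
    regional profile is defined on raw power.
    """
    if psd.scale != "raw_power":
        raise ValueError("band_power requires raw power (not dB)")
    f_lo, f_hi = band
    f = psd.frequencies_hz
    if f_lo >= f_hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    if f_lo < f[0] or f_hi > f[-1]:
        raise ValueError(f"band [{f_lo}, {f_hi}] outside grid range [{f[0]}, {f[-1]}]")
    mask = (f >= f_lo) & (f <= f_hi)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than two grid points")
    values = np.trapezoid(psd.values[:, mask], f[mask], axis=1)
    return SpatialProfile(psd.region_labels, values)
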