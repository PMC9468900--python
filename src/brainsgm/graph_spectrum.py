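"""Frequency-dependent complex Laplacian of a structural connectome.

Axonal conduction delays d/v become phase factors exp(-i*omega*d/v) in the
frequency domain, so the connectome's adjacency acquires a frequency-dependent
complex phase on every edge while keeping |A*(omega)_jk| = C_jk.  The complex
Laplacian L(omega) = I - alpha * norm(A*(omega)) generalizes the normalized
graph Laplacian; its eigenmodes u_k(omega) are the spatial harmonics from
which regional spectra are assembled.

Unit conventions are centralized here: distances are stored in mm and
converted to metres, conduction speed is m/s, and omega = 2*pi*f (Hz to
rad/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .connectome_io import ConnectomeGraph

MM_PER_M = 1000.0


@dataclass(frozen=True)
class LaplacianSpec:
    """Coupling, conduction speed and degree-normalization of L(omega).

    ``symmetric_degree`` (default) uses Delta^{-1/2} A* Delta^{-1/2}, which
    keeps L(omega) complex-symmetric and reduces to the classical symmetric
    normalized Laplacian at omega=0; ``row_degree`` uses Delta^{-1} A*.
    Degrees are taken from the real weights so only edge phases vary with
    frequency.
    """

    alpha: float = 1.0
    speed_v: float = 5.0  # m/s
    normalization: str = "symmetric_degree"  # | "row_degree"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.speed_v <= 0:
            raise ValueError("speed_v must be > 0")
        if self.normalization not in ("symmetric_degree", "row_degree"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class ComplexModeSet:
    """Eigenpairs of L(omega), unit-norm, phase-fixed, sorted by |lambda_k|."""

    frequency_hz: float
    eigenvalues: np.ndarray  # (N,) complex
    eigenvectors: np.ndarray  # (N, N) complex, columns u_k


def complex_connectivity(
    graph: ConnectomeGraph, f: float, spec: LaplacianSpec
) -> np.ndarray:
    """A*(omega)_jk = C_jk * exp(-i * omega * D_jk / v), D in metres.

    At f=0 all phases are 1 and A* equals C exactly.
    """
    if f < 0:
        raise ValueError("frequency must be >= 0")
    omega = 2.0 * np.pi * f
    return graph.C * np.exp(-1j * omega * (graph.D / MM_PER_M) / spec.speed_v)


def normalized_complex_adjacency(
    graph: ConnectomeGraph, f: float, spec: LaplacianSpec
) -> np.ndarray:
    """Degree-normalized complex adjacency B(omega); L = I - alpha * B.

    B is independent of alpha, so the eigenvectors of L(omega) are those of
    B(omega) and lambda_k(L) = 1 - alpha * mu_k(B).
    """
    A = complex_connectivity(graph, f, spec)
    deg = graph.degrees()
    if np.any(deg <= 0):
        raise ValueError("zero degree node")
    if spec.normalization == "symmetric_degree":
        inv_sqrt = 1.0 / np.sqrt(deg)
        return inv_sqrt[:, None] * A * inv_sqrt[None, :]
    return A / deg[:, None]


def build_complex_laplacian(
    graph: ConnectomeGraph, f: float, spec: LaplacianSpec
) -> np.ndarray:
    """L(omega) = I - alpha * B(omega) with degrees from the real weights."""
    n = graph.n_regions
    return np.eye(n, dtype=complex) - spec.alpha * normalized_complex_adjacency(
        graph, f, spec
    )


def _phase_fix(U: np.ndarray) -> np.ndarray:
    """Rotate each column so its largest-magnitude entry is real and positive.

    Eigenvectors are only defined up to a complex phase; fixing it makes the
    outer products u_k u_k^H reproducible bit-for-bit.
    """
    idx = np.argmax(np.abs(U), axis=0)  # ties -> lowest row index
    pivots = U[idx, np.arange(U.shape[1])]
    phases = np.where(np.abs(pivots) > 0, pivots / np.abs(pivots), 1.0)
    return U / phases[None, :]


def eigendecompose(L: np.ndarray, frequency_hz: float = 0.0) -> ComplexModeSet:
    """Right eigenpairs of L, unit Hermitian norm, deterministic ordering.

    Sorted ascending by |lambda_k|, ties broken by real part then by the
    eigensolver's original index.
    """
    L = np.asarray(L, dtype=complex)
    if not np.all(np.isfinite(L)):
        raise ValueError("Laplacian contains non-finite entries")
    try:
        lam, U = scipy.linalg.eig(L)
    except Exception as exc:  # pragma: no cover - eigensolver failure is rare
        raise RuntimeError(f"eigendecomposition failed: {exc}") from exc
    U = U / np.linalg.norm(U, axis=0)
    U = _phase_fix(U)
    order = np.lexsort((np.arange(lam.size), lam.real, np.abs(lam)))
    return ComplexModeSet(frequency_hz, lam[order], U[:, order])
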