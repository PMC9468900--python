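"""Mesoscopic (local) model: Gamma impulse responses and the E-I transfer
function H_local(omega).

Each brain region hosts a linearized excitatory-inhibitory population pair
driven by a common white-noise input p:

    tau_e dx_e/dt = -x_e + g_ee f_e(*)x_e - g_ei f_i(*)x_i + p
    tau_i dx_i/dt = -x_i + g_ei f_e(*)x_e - g_ii f_i(*)x_i + p

where f(t) = (t/tau^2) exp(-t/tau) is the unit-DC-gain Gamma kernel whose
Fourier transform is F(omega) = 1/(1 + i*omega*tau)^2.  H_local(omega) is the
excitatory population's frequency response to p, obtained by solving the
2x2 linear system in Fourier space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: names of the seven free global parameters, in canonical order
FREE_PARAMETER_NAMES = ("tau_e", "tau_i", "tau_G", "g_ee", "g_ei", "g_ii", "alpha")

_POLE_ATOL = 1e-9
_STABILITY_DEN_MIN = 1e-6
_STABILITY_GAIN_MAX = 1e6


@dataclass(frozen=True)
class SGMParameters:
    """The seven global model parameters plus the fixed conduction speed.

    Time constants are in seconds, gains and the global coupling alpha are
    dimensionless, conduction speed v is in m/s and fixed (not fitted by
    default).
    """

    tau_e: float = 0.0175
    tau_i: float = 0.1025
    tau_G: float = 0.0175
    g_ee: float = 1.0
    g_ei: float = 2.5
    g_ii: float = 2.5
    alpha: float = 0.55
    speed_v: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "tau_G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("g_ee", "g_ei", "g_ii", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.speed_v <= 0:
            raise ValueError("speed_v must be > 0")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMETER_NAMES])

    @classmethod
    def from_free_values(cls, values, speed_v: float = 5.0) -> "SGMParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FREE_PARAMETER_NAMES),):
            raise ValueError(
                f"expected {len(FREE_PARAMETER_NAMES)} values, got {values.shape}"
            )
        return cls(**dict(zip(FREE_PARAMETER_NAMES, values)), speed_v=speed_v)

    def replace(self, **kwargs) -> "SGMParameters":
        return replace(self, **kwargs)


class UnstableParametersError(ValueError):
    """Raised when H_local is evaluated too close to a pole."""


def gamma_response(f, tau: float):
    """Gamma-kernel transfer F(omega) = 1/(1 + i*omega*tau)^2, omega = 2*pi*f.

    DC gain is exactly 1; |F| decreases monotonically with frequency.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 1.0 / (1.0 + 1j * 2.0 * np.pi * f * tau) ** 2


def _local_transfer_parts(f, params: SGMParameters):
    """Numerator and denominator of H_local (excitatory response)."""
    omega = 2.0 * np.pi * np.asarray(f, dtype=float)
    Fe = gamma_response(f, params.tau_e)
    Fi = gamma_response(f, params.tau_i)
    Qi = 1j * omega * params.tau_i + 1.0 + params.g_ii * Fi
    num = 1.0 - params.g_ei * Fi / Qi
    den = (
        1j * omega * params.tau_e
        + 1.0
        - params.g_ee * Fe
        + params.g_ei**2 * Fe * Fi / Qi
    )
    return num, den


def local_transfer(f, params: SGMParameters):
    """H_local(omega): excitatory output per unit white-noise input.

    Closed form from eliminating the inhibitory population:

        Q_i = i*omega*tau_i + 1 + g_ii F_i
        H   = (1 - g_ei F_i / Q_i) /
              (i*omega*tau_e + 1 - g_ee F_e + g_ei^2 F_e F_i / Q_i)

    Raises :class:`UnstableParametersError` near a pole; inference treats
    that as an infeasible point rather than a fatal error.
    """
    num, den = _local_transfer_parts(f, params)
    if np.any(np.abs(den) < _POLE_ATOL):
        raise UnstableParametersError("H_local denominator near zero (pole)")
    return num / den


def local_transfer_solve(f: float, params: SGMParameters) -> complex:
    """Independent oracle: solve the 2x2 Fourier-domain system directly.

    A(omega) [X_e; X_i] = [1; 1] with
        A = [[i*w*tau_e + 1 - g_ee F_e,  g_ei F_i],
             [-g_ei F_e,                 i*w*tau_i + 1 + g_ii F_i]]
    and H_local = X_e.  Kept separate from the closed form on purpose.
    """
    omega = 2.0 * np.pi * f
    Fe = complex(gamma_response(f, params.tau_e))
    Fi = complex(gamma_response(f, params.tau_i))
    A = np.array(
        [
            [1j * omega * params.tau_e + 1.0 - params.g_ee * Fe, params.g_ei * Fi],
            [-params.g_ei * Fe, 1j * omega * params.tau_i + 1.0 + params.g_ii * Fi],
        ]
    )
    x = np.linalg.solve(A, np.ones(2, dtype=complex))
    return complex(x[0])


def stability_check(params: SGMParameters, grid) -> tuple[bool, dict]:
    """Check H_local is pole-free and bounded on the evaluation grid.

    Fails iff min |denominator| < 1e-6 or max |H_local| > 1e6 anywhere on
    the grid; diagnostics report the offending frequency.
    """
    grid = np.asarray(grid, dtype=float)
    # DC denominator is real: 1 - g_ee + g_ei^2/(1+g_ii); a non-positive value
    # means the E-I loop gain exceeds 1 and the linearized fixed point is
    # unstable, regardless of whether the grid samples the crossing.
    dc_den = 1.0 - params.g_ee + params.g_ei**2 / (1.0 + params.g_ii)
    if dc_den <= 0:
        return False, {
            "reason": "unstable DC equilibrium (loop gain >= 1)",
            "dc_denominator": float(dc_den),
        }
    num, den = _local_transfer_parts(grid, params)
    abs_den = np.abs(den)
    i_min = int(np.argmin(abs_den))
    diagnostics = {
        "min_abs_denominator": float(abs_den[i_min]),
        "frequency_of_min_denominator_hz": float(grid[i_min]),
    }
    if abs_den[i_min] < _STABILITY_DEN_MIN:
        diagnostics["reason"] = "denominator near pole"
        return False, diagnostics
    gain = np.abs(num / den)
    i_max = int(np.argmax(gain))
    diagnostics["max_abs_H"] = float(gain[i_max])
    diagnostics["frequency_of_max_gain_hz"] = float(grid[i_max])
    if gain[i_max] > _STABILITY_GAIN_MAX:
        diagnostics["reason"] = "gain exceeds bound"
        return False, diagnostics
    return True, diagnostics
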