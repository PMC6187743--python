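"""Homogeneous steady states and linear (Turing) stability analysis.

The reaction part of the model has a distinguished undifferentiated fixed
point obtained by clamping Y = 0:

    S* = c0 / gamma,   A* = nu / mu,   H* = c nu S* / mu**2,

at which production and degradation of each morphogen balance.  The full
four-variable fixed point (with the weak Y couplings rho_A, rho_H, epsilon,
d active) is found numerically.  Linearizing the reaction terms at a fixed
point and adding diffusion gives, for a perturbation ~exp(lambda t + i q x),
the eigenvalue problem

    lambda(q)  in  eig( J - q^2 diag(D_A, D_H, D_S, 0) ),

Y being non-diffusing.  The system is Turing-unstable when the q = 0 mode
is stable but some finite-q mode grows.  Note that for the branching
parameter regimes studied here the q = 0 mode itself is typically unstable
(Re lambda_max(0) > 0): the undifferentiated steady state is not a quiet
background, which is why simulations default to a quiescent low-morphogen
background instead (see :mod:`branchrd.model_core`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from branchrd.model_core import ModelParameters, reaction_rates

__all__ = [
    "SteadyState",
    "DispersionResult",
    "steady_state_clamped_Y0",
    "steady_state_full",
    "jacobian",
    "dispersion",
]


@dataclass(frozen=True)
class SteadyState:
    """A homogeneous fixed point of the local reaction system."""

    A_star: float
    H_star: float
    S_star: float
    Y_star: float
    residual: float
    mode: str  # "clamped_Y0" | "full"
    degenerate: bool = False
    # residual of the Y-equation at a clamped_Y0 point (d*A*), reported as a
    # consistency note; zero for mode="full"
    Y_equation_residual: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.A_star, self.H_star, self.S_star, self.Y_star])


@dataclass(frozen=True)
class DispersionResult:
    """Leading eigenvalue real part of the linearized system per wavenumber."""

    q_values: np.ndarray
    lambda_max_real: np.ndarray
    turing_unstable: bool
    q_peak: float

    @property
    def lambda_peak(self) -> float:
        return float(self.lambda_max_real.max())


def steady_state_clamped_Y0(params: ModelParameters) -> SteadyState:
    """Closed-form fixed point of the A/H/S subsystem with Y clamped to 0."""
    if params.mu <= 0 or params.gamma <= 0:
        raise ValueError("mu and gamma must be positive")
    S = params.c0 / params.gamma
    A = params.nu / params.mu
    H = params.c * params.nu * S / params.mu**2
    degenerate = H <= 0 or S <= 0
    if degenerate:
        residual = 0.0
    else:
        dA, dH, dS, _ = reaction_rates(A, H, S, 0.0, params)
        residual = float(max(abs(dA), abs(dH), abs(dS)))
    return SteadyState(
        A_star=float(A), H_star=float(H), S_star=float(S), Y_star=0.0,
        residual=residual, mode="clamped_Y0", degenerate=bool(degenerate),
        Y_equation_residual=float(params.d * A),
    )


def y_nullcline_roots(params: ModelParameters, A_val: float = 0.0) -> np.ndarray:
    """Real nonnegative roots of d*A - e*Y + Y^2/(1+f*Y^2) = 0 in Y.

    Clearing the denominator gives a cubic; with A = 0 the nonzero roots
    solve f*e*Y^2 - Y + e = 0.  Roots are returned sorted ascending.
    """
    d, e, f = params.d, params.e, params.f
    # (dA - eY)(1+fY^2) + Y^2 = 0  ->  -ef Y^3 + (df A + 1) Y^2 - e Y + dA = 0
    coeffs = [-e * f, params.d * A_val * f + 1.0, -e, d * A_val]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-12].real
    return np.sort(real[real >= -1e-12])


def steady_state_full(
    params: ModelParameters,
    initial_guess: np.ndarray | None = None,
    tol: float = 1e-12,
) -> SteadyState:
    """Numeric fixed point of the full four-variable local system."""
    if initial_guess is None:
        base = steady_state_clamped_Y0(params)
        small = y_nullcline_roots(params, base.A_star)
        y0 = float(small[0]) if len(small) else 0.0
        initial_guess = np.array([base.A_star, max(base.H_star, 1e-8),
                                  base.S_star, y0])
    initial_guess = np.asarray(initial_guess, dtype=float)

    def f(x):
        return np.array(reaction_rates(*x, params))

    sol = optimize.root(f, initial_guess, method="hybr", tol=tol)
    residual = float(np.max(np.abs(f(sol.x))))
    if not sol.success or residual > 1e-10:
        raise RuntimeError(
            f"full steady state did not converge (residual {residual:.3e}, "
            f"last iterate {sol.x})"
        )
    A, H, S, Y = (float(v) for v in sol.x)
    return SteadyState(A_star=A, H_star=H, S_star=S, Y_star=Y,
                       residual=residual, mode="full",
                       degenerate=H <= 0 or S <= 0)


def jacobian(params: ModelParameters, steady: SteadyState) -> np.ndarray:
    """Analytic 4x4 Jacobian of the local reaction rates at a fixed point.

    Row/column order is (A, H, S, Y).
    """
    A, H, S, Y = steady.A_star, steady.H_star, steady.S_star, steady.Y_star
    if H <= 0:
        raise ValueError("Jacobian undefined at H* <= 0 (degenerate point)")
    p = params
    one_fY2 = 1.0 + p.f * Y * Y
    dYdY = -p.e + (2.0 * Y * one_fY2 - Y * Y * 2.0 * p.f * Y) / one_fY2**2
    return np.array([
        [2 * p.c * A * S / H - p.mu, -p.c * A * A * S / H**2, p.c * A * A / H, p.rho_A],
        [2 * p.c * A * S,            -p.nu,                   p.c * A * A,     p.rho_H],
        [0.0,                        0.0,                     -p.gamma - p.epsilon * Y, -p.epsilon * S],
        [p.d,                        0.0,                     0.0,             dYdY],
    ])


def dispersion(
    params: ModelParameters,
    steady: SteadyState,
    q_max: float = np.pi,
    n_q: int = 200,
) -> DispersionResult:
    """Leading growth rate Re lambda_max(q) of the linearized system.

    Eigenvalues of ``J - q^2 diag(D_A, D_H, D_S, 0)`` are computed
    numerically on ``n_q`` wavenumbers spanning [0, q_max].
    """
    J = jacobian(params, steady)
    D = np.diag([params.D_A, params.D_H, params.D_S, 0.0])
    q_values = np.linspace(0.0, q_max, n_q)
    lam = np.empty(n_q)
    for i, q in enumerate(q_values):
        lam[i] = np.max(np.linalg.eigvals(J - q * q * D).real)
    i_peak = int(np.argmax(lam))
    turing = bool(lam[0] < 0 and np.any(lam[1:] > 0))
    return DispersionResult(
        q_values=q_values,
        lambda_max_real=lam,
        turing_unstable=turing,
        q_peak=float(q_values[i_peak]),
    )
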