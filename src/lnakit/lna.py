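"""Stationary linear noise approximation about a stable steady state.

The LNA is the next-to-leading order of the system-size expansion of the
chemical master equation: writing n/Ω = x + ξ/√Ω, the fluctuations ξ are
Gaussian with stationary covariance Ξ solving the Lyapunov equation

    A Ξ + Ξ Aᵀ + B = 0,

where A is the Jacobian of the reduced macroscopic drift and
B = Σ_μ ν_μ ν_μᵀ f_μ(x*) the second-jump-moment (diffusion) matrix, both
evaluated at the fixed point x*.  Particle-number covariances are
C = Ω·Ξ, i.e. A C + C Aᵀ + Ω B = 0.  The equation is solved for the
conservation-reduced system (a unique solution needs A stable, which the
unreduced drift never is when moieties are conserved) and the full
covariance is recovered through the link matrix, C_full = L C_red Lᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .conservation import ReducedSystem, reduce
from .model import ModelError, ReactionNetwork
from .steady_state import SteadyState, find_steady_state

__all__ = [
    "LNAResult",
    "LNAError",
    "jacobian_A",
    "diffusion_B",
    "solve_lyapunov",
    "expand_covariance",
    "lna",
]


class LNAError(RuntimeError):
    """The LNA preconditions are violated (instability, reversibility...)."""


def jacobian_A(reduced: ReducedSystem, x_star, params=None) -> np.ndarray:
    """Drift matrix A_ij = Σ_μ ν_iμ ∂f_μ/∂x_j over independent species,
    with dependent densities eliminated through the conservation
    relations before differentiation."""
    return reduced.drift_jacobian(x_star, params)


def diffusion_B(reduced: ReducedSystem, x_star, params=None) -> np.ndarray:
    """Diffusion matrix B_ij = Σ_μ ν_iμ ν_jμ f_μ(x*) = N diag(f) Nᵀ."""
    x_full = np.clip(reduced.full_densities(x_star), 0.0, None)
    f = reduced.network.macroscopic_rates(x_full, params)
    return (reduced.N_red * f) @ reduced.N_red.T


def solve_lyapunov(
    A: np.ndarray, B: np.ndarray, omega: float = 1.0
) -> np.ndarray:
    """Solve A C + C Aᵀ + Ω B = 0 for C by the Bartels–Stewart (Schur)
    method.

    A must be asymptotically stable — with any eigenvalue on or right of
    the imaginary axis the stationary covariance does not exist (the
    solution of the equation is no longer unique).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    eig = np.linalg.eigvals(A)
    norm_A = max(np.max(np.abs(A)), 1e-300)
    if np.max(eig.real) > -1e-10 * norm_A:
        raise LNAError(
            f"drift matrix is not asymptotically stable "
            f"(max Re(λ) = {np.max(eig.real):.3g}); the Lyapunov solution "
            f"is not unique"
        )
    C = solve_continuous_lyapunov(A, -omega * B)
    C = 0.5 * (C + C.T)
    resid = np.max(np.abs(A @ C + C @ A.T + omega * B))
    if resid > 1e-9 * max(np.max(np.abs(omega * B)), 1e-300):
        raise LNAError(f"Lyapunov solve residual too large ({resid:.3g})")
    return C


def expand_covariance(C_red: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Recover the full covariance C = L C_red Lᵀ through a link matrix."""
    C_red = np.asarray(C_red, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.shape[1] != C_red.shape[0] or C_red.shape[0] != C_red.shape[1]:
        raise ModelError(
            f"dimension mismatch: L is {L.shape}, C_red is {C_red.shape}"
        )
    return L @ C_red @ L.T


@dataclass
class LNAResult:
    """LNA output: matrices, covariances and steady-state means.

    Covariances are particle-number scale (particles²) in the network's
    declared species order; ``Xi`` is the density-scale covariance
    C_red/Ω of the independent species.
    """

    network: ReactionNetwork
    reduced: ReducedSystem
    steady_state: SteadyState
    A: np.ndarray
    B: np.ndarray
    Xi: np.ndarray
    C_red: np.ndarray
    C_full: np.ndarray
    means: np.ndarray  # particle numbers, all K̂ species

    @property
    def species_ids(self) -> list[str]:
        return self.network.species_ids

    def _index(self, species: int | str) -> int:
        if isinstance(species, str):
            try:
                return self.network.species_index[species]
            except KeyError:
                raise KeyError(f"unknown species {species!r}") from None
        return int(species)

    def mean(self, species) -> float:
        return float(self.means[self._index(species)])

    def variance(self, species) -> float:
        i = self._index(species)
        return float(self.C_full[i, i])

    def covariance(self, a, b) -> float:
        return float(self.C_full[self._index(a), self._index(b)])


def lna(
    net: ReactionNetwork,
    parameters: dict[str, float] | None = None,
    x0=None,
) -> LNAResult:
    """Run the full LNA pipeline on a network.

    Orchestrates: conservation reduction → steady-state search → A and B
    → Lyapunov solve → covariance recovery.  ``parameters`` optionally
    overrides model parameter values for this evaluation.

    Raises
    ------
    ModelError
        If the network still contains reversible reactions.
    SteadyStateError
        If no steady state is found.
    LNAError
        If the steady state is not asymptotically stable.
    """
    if any(r.reversible for r in net.reactions):
        raise ModelError(
            "reversible reactions present; split them (split_reversible) "
            "before applying the LNA"
        )
    if parameters:
        net = net.with_parameters(parameters)
    reduced = reduce(net)
    ss = find_steady_state(reduced, x0=x0)
    if not ss.stable:
        raise LNAError(
            f"steady state is unstable (max Re(λ) = {ss.max_real_eigenvalue:.3g})"
        )
    A = ss.jacobian
    B = diffusion_B(reduced, ss.x_red)
    C_red = solve_lyapunov(A, B, net.system_size)
    C_full = expand_covariance(C_red, reduced.link_matrix_original)
    return LNAResult(
        network=net,
        reduced=reduced,
        steady_state=ss,
        A=A,
        B=B,
        Xi=C_red / net.system_size,
        C_red=C_red,
        C_full=C_full,
        means=ss.mean_particles,
    )
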